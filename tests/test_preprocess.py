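"""Schedule, grid alignment, composite, compliance, exclusions, regridding."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esmvar.preprocess import (
    EsmGrid,
    apply_exclusions,
    build_grid,
    build_schedule,
    compose_self_esteem,
    compute_compliance,
    grids_to_long,
    long_to_grids,
    read_long,
    regrid,
    write_long,
)


def _resp(pid, hh, mm, arousal=5.0, worth=5.0, worthless=5.0, group=1):
    return {
        "participant_id": pid,
        "group": group,
        "timestamp": dt.datetime(2000, 1, 1, hh, mm),
        "arousal": arousal,
        "se_worth": worth,
        "se_worthless": worthless,
    }


class TestBuildSchedule:
    @pytest.mark.parametrize(
        "start,end,interval,expected",
        [
            (dt.time(8), dt.time(21), 15, 52),  # the study design
            (dt.time(8), dt.time(9), 15, 4),
            (dt.time(8), dt.time(21), 30, 26),
        ],
    )
    def test_slot_counts(self, start, end, interval, expected):
        assert len(build_schedule(start, end, interval)) == expected

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            build_schedule(interval_min=0)
        with pytest.raises(ValueError):
            build_schedule(dt.time(9), dt.time(8), 15)
        with pytest.raises(ValueError, match="divide"):
            build_schedule(dt.time(8), dt.time(21), 7)


class TestBuildGrid:
    def test_gap_between_responses_yields_missing_slots(self):
        # answering at 9:15 and 10:00 leaves the 9:30 and 9:45 slots missing
        df = pd.DataFrame([_resp("p1", 9, 15), _resp("p1", 10, 0)])
        grids, _ = build_grid(df)
        g = grids[0]
        sched = build_schedule()
        idx = {t: k for k, t in enumerate(sched)}
        assert g.valid[idx[dt.time(9, 15)]]
        assert not g.valid[idx[dt.time(9, 30)]]
        assert not g.valid[idx[dt.time(9, 45)]]
        assert g.valid[idx[dt.time(10, 0)]]
        assert g.n_valid == 2

    def test_first_response_in_window_wins(self):
        df = pd.DataFrame(
            [_resp("p1", 8, 2, arousal=3.0), _resp("p1", 8, 9, arousal=9.0)]
        )
        grids, _ = build_grid(df)
        assert grids[0].arousal[0] == 3.0
        assert grids[0].n_valid == 1

    def test_empty_participant_still_emits_grid(self):
        df = pd.DataFrame([_resp("p1", 9, 0), _resp("p2", 23, 30)])
        grids, n_outside = build_grid(df)
        assert n_outside == 1
        by_id = {g.participant_id: g for g in grids}
        assert by_id["p2"].n_valid == 0
        assert by_id["p2"].n_slots == 52

    def test_order_independence(self):
        rows = [_resp("p1", 9, 1, arousal=1.0), _resp("p1", 9, 7, arousal=2.0),
                _resp("p1", 12, 30, arousal=3.0)]
        g1, _ = build_grid(pd.DataFrame(rows))
        g2, _ = build_grid(pd.DataFrame(rows[::-1]))
        np.testing.assert_array_equal(g1[0].arousal, g2[0].arousal)


class TestComposite:
    @pytest.mark.parametrize("worth,worthless,expected", [(8, 2, 8.0), (10, 0, 10.0), (5, 5, 5.0)])
    def test_examples(self, worth, worthless, expected):
        assert compose_self_esteem(worth, worthless) == expected

    def test_missing_item_propagates(self):
        assert np.isnan(compose_self_esteem(np.nan, 3.0))

    @settings(max_examples=60, derandomize=True)
    @given(
        a=st.floats(0, 10, allow_nan=False),
        b=st.floats(0, 10, allow_nan=False),
    )
    def test_reverse_coding_antisymmetry(self, a, b):
        """Swapping (a, b) -> (10-b, 10-a) leaves the composite invariant."""
        assert compose_self_esteem(a, b) == pytest.approx(
            compose_self_esteem(10 - b, 10 - a), abs=1e-9
        )


def _grid_with_valid(pid, n_valid, value=None, n_slots=52, group=1):
    rngv = np.random.default_rng(abs(hash(pid)) % 2**31)
    arous = np.full(n_slots, np.nan)
    worth = np.full(n_slots, np.nan)
    worthless = np.full(n_slots, np.nan)
    idx = np.arange(n_valid)
    arous[idx] = value if value is not None else rngv.uniform(0, 10, n_valid)
    worth[idx] = value if value is not None else rngv.uniform(0, 10, n_valid)
    worthless[idx] = value if value is not None else rngv.uniform(0, 10, n_valid)
    return EsmGrid(pid, group, arous, worth, worthless)


class TestCompliance:
    def test_percentages(self):
        grids = [_grid_with_valid("a", 26), _grid_with_valid("b", 0)]
        rep = compute_compliance(grids)
        per = rep.per_person.set_index("participant_id")
        assert per.loc["a", "pct_valid"] == pytest.approx(50.0)
        assert per.loc["b", "pct_valid"] == 0.0

    def test_group_mean_matches_observed_compliance_scale(self):
        # a group averaging 23.5 valid responses sits at 45.19% of 52
        grids = [_grid_with_valid("a", 23), _grid_with_valid("b", 24)]
        rep = compute_compliance(grids)
        assert rep.per_group.loc[0, "mean_valid"] == pytest.approx(23.5)
        assert rep.per_group.loc[0, "mean_pct"] == pytest.approx(45.19, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_compliance([])


class TestExclusions:
    def test_low_compliance_boundary(self):
        grids = [_grid_with_valid("nine", 9), _grid_with_valid("ten", 10)]
        kept, log = apply_exclusions(grids, min_valid=10)
        assert [g.participant_id for g in kept] == ["ten"]
        assert log.iloc[0]["reason"] == "low_compliance"

    def test_zero_variance_excluded(self):
        grids = [_grid_with_valid("flat", 20, value=5.0), _grid_with_valid("ok", 20)]
        kept, log = apply_exclusions(grids)
        assert [g.participant_id for g in kept] == ["ok"]
        assert log.iloc[0]["reason"] == "zero_variance"


class TestRegrid:
    def test_complete_grid_halves(self):
        g = _grid_with_valid("a", 52)
        out = regrid(g, 2)
        assert out.n_slots == 26
        assert out.n_valid == 26
        assert out.interval_min == 30

    def test_first_valid_rule(self):
        arous = np.full(4, np.nan)
        arous[1] = 7.0  # only the second fine slot of the first pair observed
        arous[2] = 3.0
        g = EsmGrid("a", 1, arous, arous.copy(), arous.copy())
        out = regrid(g, 2)
        assert out.arousal[0] == 7.0
        assert out.arousal[1] == 3.0

    def test_factor_four(self):
        g = _grid_with_valid("a", 52)
        assert regrid(g, 4).n_slots == 13

    def test_unsupported_factor(self):
        with pytest.raises(ValueError):
            regrid(_grid_with_valid("a", 52), 3)


class TestLongRoundTrip:
    def test_grid_long_grid_identity(self, tmp_path, bpd_missing_dataset):
        grids = bpd_missing_dataset["grids"][:5]
        df = grids_to_long(grids, include_missing=True)
        path = tmp_path / "grid.csv"
        write_long(df, path)
        back = long_to_grids(read_long(path))
        for g, h in zip(grids, back):
            assert g.participant_id == h.participant_id
            np.testing.assert_allclose(g.arousal, h.arousal, atol=1e-9)
            np.testing.assert_allclose(g.composite, h.composite, atol=1e-9)

    def test_raw_responses_rebuild_grid(self, bpd_missing_dataset):
        """Timestamped raw export -> build_grid reproduces the slot layout."""
        grids = bpd_missing_dataset["grids"][:5]
        raw = grids_to_long(grids, include_missing=False)
        rebuilt, n_outside = build_grid(raw)
        assert n_outside == 0
        for g, h in zip(grids, sorted(rebuilt, key=lambda x: x.participant_id)):
            np.testing.assert_array_equal(g.valid, h.valid)
            np.testing.assert_allclose(
                g.arousal[g.valid], h.arousal[h.valid], atol=1e-9
            )


def test_wide_by_slot_dialect(bpd_missing_dataset):
    from esmvar.preprocess import grids_to_wide

    grids = bpd_missing_dataset["grids"][:4]
    wide = grids_to_wide(grids)
    assert len(wide) == 4
    assert wide.shape[1] == 2 + 4 * 52
    g = grids[0]
    row = wide.iloc[0]
    k = int(np.flatnonzero(g.valid)[0])
    assert row[f"arousal_{k:02d}"] == pytest.approx(g.arousal[k])
    assert np.isnan(row[f"arousal_{int(np.flatnonzero(~g.valid)[0]):02d}"])
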