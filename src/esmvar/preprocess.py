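"""Raw e-diary responses -> equidistant analysis grid.

The study design prompts participants 52 times per day, every 15 minutes
from 8 am to 9 pm.  Participants may answer on demand, so raw responses
carry wall-clock timestamps rather than prompt indices.  A *valid response*
is the first entry whose timestamp falls inside a quarter-hour slot window;
later entries in the same window are dropped and empty windows become
explicit missing rows, so every participant contributes exactly 52
equidistant rows to the analysis table.

Momentary self-esteem is measured with two items ("I am a valuable person"
and "I am worthless", both 0-10); the analysed score is the occasion mean of
the first item and the reverse-coded second item.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RATING_MIN, RATING_MAX = 0.0, 10.0

#: study defaults: 8 am - 9 pm at 15-minute spacing -> 52 slots
DEFAULT_START = dt.time(8, 0)
DEFAULT_END = dt.time(21, 0)
DEFAULT_INTERVAL_MIN = 15

LONG_COLUMNS = (
    "participant_id",
    "group",
    "slot_index",
    "timestamp",
    "arousal",
    "se_worth",
    "se_worthless",
)


def compose_self_esteem(se_worth, se_worthless):
    """Two-item composite: mean of item 1 and reverse-coded item 2.

    ``(se_worth + (10 - se_worthless)) / 2``; missing (NaN) in either item
    propagates to the composite.
    """
    return (np.asarray(se_worth, dtype=float) + (RATING_MAX - np.asarray(se_worthless, dtype=float))) / 2.0


def build_schedule(
    start: dt.time = DEFAULT_START,
    end: dt.time = DEFAULT_END,
    interval_min: int = DEFAULT_INTERVAL_MIN,
) -> list[dt.time]:
    """Slot start times for the prompting window.

    The window ``[start, end)`` is tiled with contiguous half-open bins of
    ``interval_min`` minutes; the study defaults give exactly 52 slots.
    """
    if interval_min <= 0:
        raise ValueError("interval_min must be positive")
    start_m = start.hour * 60 + start.minute
    end_m = end.hour * 60 + end.minute
    if end_m <= start_m:
        raise ValueError("end must be after start")
    span = end_m - start_m
    if span % interval_min != 0:
        raise ValueError(
            f"interval of {interval_min} min does not divide the {span} min window"
        )
    return [
        dt.time((start_m + k * interval_min) // 60, (start_m + k * interval_min) % 60)
        for k in range(span // interval_min)
    ]


@dataclass
class EsmGrid:
    """One participant's responses aligned to the equidistant slot grid.

    Arrays all have length ``n_slots``; unanswered slots hold NaN.  The
    composite is defined only where both self-esteem items were observed.
    ``group`` uses the study coding 1 = BPD, 2 = DD, 3 = NCC.
    """

    participant_id: str
    group: int
    arousal: np.ndarray
    se_worth: np.ndarray
    se_worthless: np.ndarray
    interval_min: int = DEFAULT_INTERVAL_MIN
    composite: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.arousal = np.asarray(self.arousal, dtype=float)
        self.se_worth = np.asarray(self.se_worth, dtype=float)
        self.se_worthless = np.asarray(self.se_worthless, dtype=float)
        if not (self.arousal.shape == self.se_worth.shape == self.se_worthless.shape):
            raise ValueError("item arrays must share one length")
        if self.composite is None:
            self.composite = compose_self_esteem(self.se_worth, self.se_worthless)
        else:
            self.composite = np.asarray(self.composite, dtype=float)

    @property
    def n_slots(self) -> int:
        return int(self.arousal.shape[0])

    @property
    def valid(self) -> np.ndarray:
        """Slots with any observed rating (an answered prompt)."""
        return (
            ~np.isnan(self.arousal)
            | ~np.isnan(self.se_worth)
            | ~np.isnan(self.se_worthless)
        )

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def _time_to_min(t) -> float:
    if isinstance(t, dt.datetime) or isinstance(t, pd.Timestamp):
        t = t.time()
    return t.hour * 60 + t.minute + t.second / 60.0


def build_grid(
    responses: pd.DataFrame,
    schedule: list[dt.time] | None = None,
    groups: dict[str, int] | None = None,
    interval_min: int | None = None,
) -> tuple[list[EsmGrid], int]:
    """Align raw time-stamped responses onto the slot grid.

    Parameters
    ----------
    responses : long frame with columns ``participant_id, timestamp,
        arousal, se_worth, se_worthless`` and optionally ``group``.
    schedule : slot start times from :func:`build_schedule` (study default
        when omitted).
    groups : optional ``participant_id -> group code`` mapping overriding /
        replacing a ``group`` column.

    Returns
    -------
    (grids, n_outside) : one grid per participant (participants sorted by
        id; responses sorted by timestamp within participant, making the
        construction order-independent) and the count of responses falling
        outside the prompting window, which are ignored.
    """
    if schedule is None:
        schedule = build_schedule()
    if interval_min is None:
        interval_min = (
            _time_to_min(schedule[1]) - _time_to_min(schedule[0])
            if len(schedule) > 1
            else DEFAULT_INTERVAL_MIN
        )
    starts = np.array([_time_to_min(t) for t in schedule], dtype=float)
    n_slots = len(schedule)
    lo, hi = starts[0], starts[-1] + interval_min

    df = responses.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values(["participant_id", "timestamp"], kind="stable")
    all_pids = df["participant_id"].astype(str)
    pid_group = {}
    if groups is not None:
        pid_group = {str(k): int(v) for k, v in groups.items()}
    elif "group" in df.columns:
        pid_group = {str(p): int(g) for p, g in zip(all_pids, df["group"])}
    minutes = df["timestamp"].map(_time_to_min).to_numpy(dtype=float)
    inside = (minutes >= lo) & (minutes < hi)
    n_outside = int((~inside).sum())
    if n_outside:
        logger.info("ignored %d responses outside the prompting window", n_outside)
    df = df.loc[inside]
    minutes = minutes[inside.to_numpy() if hasattr(inside, "to_numpy") else inside]
    slot = np.floor((minutes - lo) / interval_min).astype(int)
    df = df.assign(_slot=slot)

    grids: list[EsmGrid] = []
    seen: set[str] = set()
    for pid, sub in df.groupby("participant_id", sort=True):
        seen.add(str(pid))
        arous = np.full(n_slots, np.nan)
        worth = np.full(n_slots, np.nan)
        worthless = np.full(n_slots, np.nan)
        # first response per window wins
        first = sub.drop_duplicates("_slot", keep="first")
        idx = first["_slot"].to_numpy()
        arous[idx] = first["arousal"].to_numpy(dtype=float)
        worth[idx] = first["se_worth"].to_numpy(dtype=float)
        worthless[idx] = first["se_worthless"].to_numpy(dtype=float)
        if groups is not None:
            grp = int(groups[pid])
        elif "group" in sub.columns:
            grp = int(sub["group"].iloc[0])
        else:
            grp = 0
        for name, arr in (("arousal", arous), ("se_worth", worth), ("se_worthless", worthless)):
            bad = np.flatnonzero((arr < RATING_MIN - 1e-9) | (arr > RATING_MAX + 1e-9))
            if bad.size:
                logger.warning(
                    "participant %s: %d %s ratings outside [0, 10]", pid, bad.size, name
                )
        grids.append(
            EsmGrid(
                participant_id=str(pid),
                group=grp,
                arousal=arous,
                se_worth=worth,
                se_worthless=worthless,
                interval_min=int(interval_min),
            )
        )
    # participants whose every response fell outside the window still get a
    # (fully missing) grid -- they exist in the raw file
    empty = np.full(n_slots, np.nan)
    for pid in sorted(set(all_pids) - seen):
        grids.append(
            EsmGrid(
                participant_id=pid,
                group=pid_group.get(pid, 0),
                arousal=empty.copy(),
                se_worth=empty.copy(),
                se_worthless=empty.copy(),
                interval_min=int(interval_min),
            )
        )
    grids.sort(key=lambda g: g.participant_id)
    return grids, n_outside


@dataclass
class ComplianceReport:
    """Valid-response accounting for a set of grids."""

    per_person: pd.DataFrame  # participant_id, group, n_valid, pct_valid
    per_group: pd.DataFrame  # group, n_persons, mean_valid, mean_pct, sd_valid
    slot_missing: np.ndarray  # fraction missing per slot, pooled


def compute_compliance(grids: list[EsmGrid]) -> ComplianceReport:
    """Per-person valid counts and per-group compliance summaries."""
    if not grids:
        raise ValueError("no grids supplied")
    n_slots = grids[0].n_slots
    rows = [
        {
            "participant_id": g.participant_id,
            "group": g.group,
            "n_valid": g.n_valid,
            "pct_valid": 100.0 * g.n_valid / g.n_slots,
        }
        for g in grids
    ]
    per_person = pd.DataFrame(rows)
    per_group = (
        per_person.groupby("group")
        .agg(
            n_persons=("n_valid", "size"),
            mean_valid=("n_valid", "mean"),
            mean_pct=("pct_valid", "mean"),
            sd_valid=("n_valid", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
        )
        .reset_index()
    )
    missing = np.mean([~g.valid for g in grids], axis=0)
    return ComplianceReport(per_person=per_person, per_group=per_group, slot_missing=missing)


def apply_exclusions(
    grids: list[EsmGrid], min_valid: int = 10
) -> tuple[list[EsmGrid], pd.DataFrame]:
    """Study exclusion rules.

    Participants answering fewer than ``min_valid`` of the scheduled prompts
    are removed (low compliance), as are participants whose observed e-diary
    ratings are constant across all three item streams jointly (zero
    variance).  Returns the retained grids and a log with one row per
    excluded participant.
    """
    kept: list[EsmGrid] = []
    log_rows = []
    for g in grids:
        if g.n_valid < min_valid:
            log_rows.append(
                {
                    "participant_id": g.participant_id,
                    "group": g.group,
                    "reason": "low_compliance",
                    "n_valid": g.n_valid,
                }
            )
            continue
        observed = np.concatenate(
            [
                g.arousal[~np.isnan(g.arousal)],
                g.se_worth[~np.isnan(g.se_worth)],
                g.se_worthless[~np.isnan(g.se_worthless)],
            ]
        )
        if observed.size and np.ptp(observed) == 0.0:
            log_rows.append(
                {
                    "participant_id": g.participant_id,
                    "group": g.group,
                    "reason": "zero_variance",
                    "n_valid": g.n_valid,
                }
            )
            continue
        kept.append(g)
    log = pd.DataFrame(log_rows, columns=["participant_id", "group", "reason", "n_valid"])
    return kept, log


def regrid(grid: EsmGrid, factor: int) -> EsmGrid:
    """Coarsen the grid to 30- or 60-minute spacing (factor 2 or 4).

    Coarse slot *k* takes the first fine slot inside its window that holds a
    valid response; windows without any valid fine slot stay missing.
    """
    if factor not in (2, 4):
        raise ValueError("factor must be 2 (30 min) or 4 (60 min)")
    n_fine = grid.n_slots
    n_coarse = n_fine // factor
    arrays = {}
    valid = grid.valid
    for name in ("arousal", "se_worth", "se_worthless"):
        arrays[name] = np.full(n_coarse, np.nan)
    for k in range(n_coarse):
        window = range(k * factor, min((k + 1) * factor, n_fine))
        for t in window:
            if valid[t]:
                arrays["arousal"][k] = grid.arousal[t]
                arrays["se_worth"][k] = grid.se_worth[t]
                arrays["se_worthless"][k] = grid.se_worthless[t]
                break
    return EsmGrid(
        participant_id=grid.participant_id,
        group=grid.group,
        arousal=arrays["arousal"],
        se_worth=arrays["se_worth"],
        se_worthless=arrays["se_worthless"],
        interval_min=grid.interval_min * factor,
    )


# ---------------------------------------------------------------------------
# long-format round tripping


def grids_to_long(
    grids: list[EsmGrid],
    schedule: list[dt.time] | None = None,
    include_missing: bool = True,
    date: dt.date = dt.date(2000, 1, 1),
) -> pd.DataFrame:
    """Serialise grids to the long delimited layout.

    With ``include_missing=True`` every participant contributes one row per
    slot ("52 rows per person"); otherwise only answered prompts appear
    (the raw-response layout).
    """
    if schedule is None and grids:
        schedule = build_schedule(interval_min=grids[0].interval_min)
    rows = []
    for g in grids:
        for k in range(g.n_slots):
            is_valid = bool(g.valid[k])
            if not include_missing and not is_valid:
                continue
            ts = dt.datetime.combine(date, schedule[k]) if schedule else None
            rows.append(
                {
                    "participant_id": g.participant_id,
                    "group": g.group,
                    "slot_index": k,
                    "timestamp": ts.isoformat() if ts else "",
                    "arousal": g.arousal[k],
                    "se_worth": g.se_worth[k],
                    "se_worthless": g.se_worthless[k],
                }
            )
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


def grids_to_wide(grids: list[EsmGrid]) -> pd.DataFrame:
    """Wide-by-slot dialect: one row per participant, one column per slot
    and variable (``arousal_00`` ... ``composite_51``)."""
    rows = []
    for g in grids:
        row: dict = {"participant_id": g.participant_id, "group": g.group}
        for name, arr in (
            ("arousal", g.arousal),
            ("se_worth", g.se_worth),
            ("se_worthless", g.se_worthless),
            ("composite", g.composite),
        ):
            for k in range(g.n_slots):
                row[f"{name}_{k:02d}"] = arr[k]
        rows.append(row)
    return pd.DataFrame(rows)


def long_to_grids(df: pd.DataFrame, n_slots: int | None = None) -> list[EsmGrid]:
    """Rebuild grids from the 52-row-per-person long layout (slot-indexed)."""
    if n_slots is None:
        n_slots = int(df["slot_index"].max()) + 1
    grids = []
    for pid, sub in df.groupby("participant_id", sort=True):
        arrays = {n: np.full(n_slots, np.nan) for n in ("arousal", "se_worth", "se_worthless")}
        idx = sub["slot_index"].to_numpy(dtype=int)
        for name in arrays:
            arrays[name][idx] = sub[name].to_numpy(dtype=float)
        grids.append(
            EsmGrid(
                participant_id=str(pid),
                group=int(sub["group"].iloc[0]) if "group" in sub.columns else 0,
                **arrays,
            )
        )
    return grids


def write_long(df: pd.DataFrame, path) -> None:
    """Write the long layout as CSV; NaN becomes an empty field."""
    df.to_csv(path, index=False, na_rep="")


def read_long(path) -> pd.DataFrame:
    """Read the long CSV layout (empty fields -> NaN)."""
    return pd.read_csv(path, dtype={"participant_id": str})
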