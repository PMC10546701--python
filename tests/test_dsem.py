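"""Sampler components, diagnostics, summaries and estimator invariants."""

import numpy as np
import pytest

from esmvar import TrueParams, default_true_params
from esmvar.dsem import (
    McmcConfig,
    PosteriorDraws,
    fit_dsem,
    phi_conditional_moments,
    psr,
    r2_from_effects,
    summarize,
    within_r2,
)
from esmvar.params import MissingnessPattern
from esmvar.simulate import apply_missingness, generate_dataset

def _draws_from_array(x, names=("theta",)):
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    cfg = McmcConfig(n_chains=arr.shape[0], n_iterations=2 * arr.shape[1], seed=0)
    return PosteriorDraws(parameter_names=list(names), draws=arr, config=cfg)


class TestPsr:
    def test_identical_chains_give_one(self):
        # with zero between-chain variance the statistic is sqrt((n-1)/n)
        x = np.vstack([np.sin(np.arange(100.0))] * 2)
        assert psr(_draws_from_array(x), "theta") == pytest.approx(1.0, abs=0.01)

    def test_matches_brute_force_formula(self, rng):
        x = np.vstack(
            [rng.normal(0, 1, size=1000), rng.normal(10, 1, size=1000)]
        )
        n = x.shape[1]
        w = np.mean([np.var(c, ddof=1) for c in x])
        b = n * np.var([c.mean() for c in x], ddof=1)
        expected = np.sqrt((w * (n - 1) / n + b / n) / w)
        assert psr(x) == pytest.approx(expected, rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="two chains"):
            psr(np.zeros((1, 100)))


class TestSummarize:
    def test_constant_draws(self):
        d = _draws_from_array(np.full((2, 50), 3.0))
        s = summarize(d)
        assert s.loc["theta", "median"] == 3.0
        assert s.loc["theta", "ci_low"] == s.loc["theta", "ci_high"] == 3.0
        assert bool(s.loc["theta", "significant"])
        z = summarize(_draws_from_array(np.zeros((2, 50))))
        assert not bool(z.loc["theta", "significant"])

    def test_symmetric_draws_not_significant(self, rng):
        x = rng.normal(0, 1, size=(2, 400))
        s = summarize(_draws_from_array(x))
        assert not bool(s.loc["theta", "significant"])

    def test_percentile_ci_matches_sorted_array_oracle(self, rng):
        x = rng.normal(2.0, 1.0, size=(2, 500))
        s = summarize(_draws_from_array(x))
        pooled = np.sort(x.reshape(-1))
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        assert s.loc["theta", "ci_low"] == pytest.approx(lo, rel=1e-12)
        assert s.loc["theta", "ci_high"] == pytest.approx(hi, rel=1e-12)
        assert s.loc["theta", "median"] == pytest.approx(np.median(pooled), rel=1e-12)

    def test_empty_draws_rejected(self):
        d = _draws_from_array(np.zeros((2, 50)))
        d.draws = d.draws[:, :0, :]
        with pytest.raises(ValueError):
            summarize(d)


class TestWithinR2:
    def test_no_dynamics_means_zero(self):
        eta = np.array([0, 0, 0, 0, 0, 0, 0.3, -0.2, 0.1])
        np.testing.assert_allclose(r2_from_effects(eta), [0.0, 0.0], atol=1e-12)

    def test_univariate_ar_closed_form(self):
        # diagonal Phi, no cross-lags: R^2 = phi^2
        eta = np.array([0, 0, 0.5, 0.3, 0, 0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(r2_from_effects(eta), [0.25, 0.09], atol=1e-12)

    def test_monotone_in_ar_strength(self):
        vals = [r2_from_effects(np.array([0, 0, phi, 0.2, 0, 0, 0, 0, 0]))[0]
                for phi in (0.1, 0.3, 0.5, 0.7)]
        assert np.all(np.diff(vals) > 0)


class TestPhiConditional:
    def test_concentrates_on_ols_solution(self, rng):
        """With a flat prior and tiny innovation variance the conditional
        posterior mean of the transition parameters is the lag-1 OLS fit."""
        n, T = 3, 60
        W = rng.normal(0, 1, size=(n, T, 2))
        v = 1e-6
        siginv = (np.full(n, 1 / v), np.zeros(n), np.full(n, 1 / v))
        mean, prec = phi_conditional_moments(
            W, siginv, prior_mean=np.zeros((n, 4)), prior_prec=1e-12 * np.eye(4)
        )
        for i in range(n):
            X, Y = W[i, :-1, :], W[i, 1:, :]
            beta = np.linalg.lstsq(X, Y, rcond=None)[0]  # (2, 2): beta[j, c]
            ols_theta = np.array([beta[0, 0], beta[1, 0], beta[0, 1], beta[1, 1]])
            np.testing.assert_allclose(mean[i], ols_theta, atol=1e-6)


class TestFitDsem:
    def test_null_model_covers_zero(self):
        """White-noise data with no heterogeneity: all four dynamic fixed
        effects get CIs covering zero."""
        tp = default_true_params("null")
        tp = TrueParams(group_labels=("G",), group_means=tp.group_means[:1],
                        omega=np.zeros((9, 9)), n_per_group=(15,), n_occasions=52)
        data = generate_dataset(tp, None, seed=8)
        cfg = McmcConfig(n_chains=2, n_iterations=400, seed=1)
        s = summarize(fit_dsem(data["grids"], config=cfg))
        for p in ("phi_arousal", "phi_selfesteem",
                  "phi_se_on_arousal_lag", "phi_arousal_on_se_lag"):
            row = s.loc[f"gamma_{p}"]
            assert row["ci_low"] <= 0.0 <= row["ci_high"], p

    def test_recovery_with_missingness(self, bpd_missing_dataset, bpd_params):
        cfg = McmcConfig(n_chains=2, n_iterations=600, n_burn_in=250, seed=2)
        s = summarize(fit_dsem(bpd_missing_dataset["grids"], config=cfg))
        truth = bpd_params.group_means[0]
        for i, name in enumerate(
            ("mu_arousal", "mu_selfesteem", "phi_arousal", "phi_selfesteem")
        ):
            row = s.loc[f"gamma_{name}"]
            assert row["ci_low"] - 0.1 <= truth[i] <= row["ci_high"] + 0.1, name

    def test_deterministic_given_seed(self, bpd_complete_dataset):
        cfg = McmcConfig(n_chains=2, n_iterations=120, seed=5)
        grids = bpd_complete_dataset["grids"][:6]
        d1 = fit_dsem(grids, config=cfg)
        d2 = fit_dsem(grids, config=cfg)
        np.testing.assert_array_equal(d1.draws, d2.draws)

    def test_mcar_insensitivity(self, bpd_complete_dataset):
        """Estimates from complete vs 30%-MCAR-deleted versions of the same
        data agree within Monte-Carlo error."""
        grids = bpd_complete_dataset["grids"]
        pat = MissingnessPattern(mode="mcar", overall_rate=0.3)
        deleted = [apply_missingness(g, pat, seed=100 + i) for i, g in enumerate(grids)]
        cfg = McmcConfig(n_chains=2, n_iterations=500, n_burn_in=200, seed=3)
        s_full = summarize(fit_dsem(grids, config=cfg))
        s_del = summarize(fit_dsem(deleted, config=cfg))
        for name, tol in (
            ("gamma_mu_arousal", 0.25),
            ("gamma_mu_selfesteem", 0.25),
            ("gamma_phi_arousal", 0.12),
            ("gamma_phi_se_on_arousal_lag", 0.10),
        ):
            assert abs(s_full.loc[name, "median"] - s_del.loc[name, "median"]) < tol, name

    def test_all_missing_person_dropped_with_warning(self, bpd_complete_dataset):
        grids = list(bpd_complete_dataset["grids"][:5])
        empty = apply_missingness(
            grids[0], MissingnessPattern(mode="mcar", overall_rate=1.0), seed=0
        )
        cfg = McmcConfig(n_chains=1, n_iterations=60, seed=0)
        with pytest.warns(RuntimeWarning, match="no observed responses"):
            d = fit_dsem(grids[1:] + [empty], config=cfg)
        assert d.meta["n_persons"] == 4

    def test_mismatched_slot_counts_rejected(self, bpd_complete_dataset):
        from esmvar.preprocess import regrid
        g = bpd_complete_dataset["grids"]
        with pytest.raises(ValueError, match="slot count"):
            fit_dsem([g[0], regrid(g[1], 2)])

    def test_within_r2_summary_shape(self, small_fit):
        r2 = within_r2(small_fit)
        assert list(r2.index) == ["r2_arousal", "r2_selfesteem"]
        assert ((r2["median"] > 0) & (r2["median"] < 1)).all()

    def test_small_fit_converged(self, small_fit):
        s = summarize(small_fit)
        assert np.nanmax(s["psr"].to_numpy()) < 1.2
        # MH acceptance in a healthy band after adaptation
        for acc in small_fit.meta["mh_acceptance"]:
            assert 0.1 < acc < 0.6


def test_draws_round_trip_csv(small_fit, tmp_path):
    """Chains persist to a delimited table and reload identically."""
    path = tmp_path / "draws.csv"
    small_fit.save(path)
    from esmvar.dsem import PosteriorDraws
    back = PosteriorDraws.load(path)
    assert back.parameter_names == small_fit.parameter_names
    np.testing.assert_allclose(back.draws, small_fit.draws, rtol=1e-12)
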