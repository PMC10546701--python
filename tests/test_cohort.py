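"""Cohort statistics against printed values, scipy and brute-force oracles."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from esmvar.cohort import (
    chisq_2x2,
    fisher_exact,
    odds_ratio_wald,
    oneway_anova_omega,
    tukey_hsd,
)

# comorbidity and medication tables from the cohort description
PTSD_TABLE = [[14, 28], [4, 36]]  # PTSD yes/no in BPD (42) vs DD (40)
MEDICATION_TABLE = [[27, 13], [27, 15]]  # medicated yes/no, DD odds on top


class TestChisq:
    def test_ptsd_table_yates(self):
        stat, df, p = chisq_2x2(PTSD_TABLE)
        assert stat == pytest.approx(5.22, abs=0.005)
        assert df == 1
        assert p == pytest.approx(0.022, abs=0.002)

    def test_medication_table_yates(self):
        stat, _, p = chisq_2x2(MEDICATION_TABLE)
        assert stat == pytest.approx(0.01, abs=0.005)
        assert p > 0.9

    def test_proportional_table_is_zero(self):
        stat, _, _ = chisq_2x2([[10, 20], [20, 40]], corrected=False)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy(self):
        for table in (PTSD_TABLE, MEDICATION_TABLE, [[3, 9], [8, 4]]):
            stat, _, p = chisq_2x2(table)
            ref = scipy.stats.chi2_contingency(np.asarray(table), correction=True)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_margin_flagged(self):
        with pytest.warns(RuntimeWarning, match="zero margin"):
            stat, _, _ = chisq_2x2([[0, 0], [5, 5]])
        assert np.isnan(stat)

    def test_row_and_column_swap_invariance(self):
        a, *_ = chisq_2x2(PTSD_TABLE)
        b, *_ = chisq_2x2([[36, 4], [28, 14]])
        assert a == pytest.approx(b, rel=1e-12)


class TestOddsRatio:
    def test_ptsd_or(self):
        or_, (lo, hi) = odds_ratio_wald(PTSD_TABLE)
        assert or_ == pytest.approx(4.50, abs=0.005)
        assert lo == pytest.approx(1.33, abs=0.005)
        assert hi == pytest.approx(15.18, abs=0.005)

    def test_medication_or_dd_numerator(self):
        or_, (lo, hi) = odds_ratio_wald(MEDICATION_TABLE)
        assert or_ == pytest.approx(1.15, abs=0.005)
        assert lo == pytest.approx(0.46, abs=0.005)
        assert hi == pytest.approx(2.88, abs=0.005)

    def test_balanced_table(self):
        or_, _ = odds_ratio_wald([[10, 10], [10, 10]])
        assert or_ == 1.0

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.integers(1, 30), min_size=4, max_size=4))
    def test_inversion_symmetry(self, cells):
        """Swapping the columns within both rows inverts the OR and its CI."""
        a, b, c, d = cells
        or1, (lo1, hi1) = odds_ratio_wald([[a, b], [c, d]])
        or2, (lo2, hi2) = odds_ratio_wald([[b, a], [d, c]])
        assert or2 == pytest.approx(1.0 / or1, rel=1e-9)
        assert lo2 == pytest.approx(1.0 / hi1, rel=1e-9)
        assert hi2 == pytest.approx(1.0 / lo1, rel=1e-9)

    def test_zero_cell_correction(self):
        with pytest.warns(RuntimeWarning, match="Haldane"):
            or_, _ = odds_ratio_wald([[0, 10], [5, 5]])
        assert or_ > 0


class TestFisherExact:
    def test_empty_column_gives_one(self):
        assert fisher_exact([[5, 0], [7, 0]]) == pytest.approx(1.0)

    @settings(max_examples=80, derandomize=True)
    @given(st.lists(st.integers(0, 8), min_size=4, max_size=4))
    def test_matches_scipy_2x2(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        ours = fisher_exact([[a, b], [c, d]])
        ref = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_gender_table_printed_counts(self):
        """Female/male counts per diagnostic group; exact p on the printed
        35/42, 27/40, 31/39 counts (0.2269, matching R's fisher.test) and on
        the margin-consistent 31/40 variant (0.247, the published value)."""
        assert fisher_exact([[35, 27, 31], [7, 13, 8]]) == pytest.approx(0.2269, abs=0.0005)
        assert fisher_exact([[35, 27, 31], [7, 13, 9]]) == pytest.approx(0.247, abs=0.0005)

    def test_size_cap(self):
        with pytest.raises(ValueError, match="too large"):
            fisher_exact(np.full((4, 4), 300), max_tables=1000)


class TestAnovaOmega:
    def test_identical_groups(self):
        g = [np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4])]
        res = oneway_anova_omega(g)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.omega_sq == 0.0

    def test_f_matches_scipy(self, rng):
        groups = [rng.normal(m, 1, size=12) for m in (0.0, 0.4, 1.0)]
        res = oneway_anova_omega(groups)
        ref = scipy.stats.f_oneway(*groups)
        assert res.f == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_omega_sq_brute_force_toy_table(self):
        """Direct sums-of-squares computation on a 3x5 table."""
        groups = [np.array([1.0, 2, 3, 4, 5]),
                  np.array([2.0, 3, 4, 5, 6]),
                  np.array([4.0, 5, 6, 7, 8])]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(5 * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        msw = ssw / 12
        expected = (ssb - 2 * msw) / (ssb + ssw + msw)
        res = oneway_anova_omega(groups)
        assert res.omega_sq == pytest.approx(expected, rel=1e-12)
        assert res.omega_sq_ci[0] <= res.omega_sq <= res.omega_sq_ci[1]

    def test_omega_sq_recovers_population_value(self, rng):
        """Three groups with known standardized separation."""
        # population omega^2 = var(means) / (var(means) + var(error))
        means = np.array([-0.5, 0.0, 0.5])
        pop = means.var() / (means.var() + 1.0)
        vals = [oneway_anova_omega(
            [rng.normal(m, 1.0, size=200) for m in means]).omega_sq
            for _ in range(10)]
        assert np.mean(vals) == pytest.approx(pop, abs=0.03)


class TestTukey:
    def test_identical_groups_p_near_one(self):
        g = np.array([1.0, 2, 3, 4, 5])
        out = tukey_hsd([g, g.copy()])
        assert out.iloc[0]["difference"] == 0.0
        assert out.iloc[0]["p"] > 0.99

    def test_balanced_ci_matches_studentized_range_oracle(self, rng):
        groups = [rng.normal(m, 1, size=10) for m in (0.0, 0.5, 1.2)]
        out = tukey_hsd(groups)
        n = 10
        df = 3 * (n - 1)
        msw = np.mean([np.var(g, ddof=1) for g in groups])
        q = scipy.stats.studentized_range.ppf(0.95, 3, df)
        half = q * np.sqrt(msw / n)
        for _, row in out.iterrows():
            assert row["ci_low"] == pytest.approx(row["difference"] - half, abs=1e-8)
            assert row["ci_high"] == pytest.approx(row["difference"] + half, abs=1e-8)

    def test_separated_groups_all_significant(self, rng):
        groups = [rng.normal(m, 0.5, size=15) for m in (0.0, 5.0, 10.0)]
        out = tukey_hsd(groups)
        assert (out["p"] < 0.001).all()
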