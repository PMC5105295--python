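"""Association statistics: HWE, exact Fisher tests, trend test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.stats import multivariate_hypergeom

from trioprio.assoc_stats import (
    GenotypeCountTable,
    _trend_statistic,
    armitage_trend,
    fisher_exact_2x3,
    fisher_exact_allele_2x2,
    genotype_frequencies,
    hwe_chisq,
)

from conftest import fisher_2xk_oracle


class TestHWE:
    def test_exact_hwe_proportions_give_zero_chi2(self):
        r = hwe_chisq((49, 42, 9))
        assert r.allele_freq == pytest.approx(0.7)
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_symmetric_half_frequency(self):
        assert hwe_chisq((25, 50, 25)).chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_departure(self):
        # n=100, p=0.45, expected (20.25, 49.5, 30.25):
        # 9.75^2/20.25 + 19.5^2/49.5 + 9.75^2/30.25 = 15.5188246...
        r = hwe_chisq((30, 30, 40))
        assert r.allele_freq == pytest.approx(0.45)
        assert r.chi2 == pytest.approx(15.5188246, rel=1e-6)
        assert r.df == 1
        assert r.p_value == pytest.approx(sps.chi2.sf(15.5188246, 1), rel=1e-6)

    def test_monomorphic_flagged(self):
        r = hwe_chisq((100, 0, 0))
        assert r.chi2 == 0.0 and r.p_value == 1.0
        assert "monomorphic" in r.flags

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            hwe_chisq((0, 0, 0))


class TestGenotypeCountTable:
    def test_allele_collapse_arithmetic(self):
        t = GenotypeCountTable(cases=(49, 42, 9), controls=(1, 0, 0))
        assert t.allele_counts()[0] == (140, 60)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            GenotypeCountTable(cases=(-1, 0, 2), controls=(1, 1, 1))

    def test_frequencies_sum_to_100(self):
        t = GenotypeCountTable(cases=(0, 0, 10), controls=(96, 4, 0))
        f = genotype_frequencies(t)
        assert f["cases"] == (0, 0, 100)
        assert f["controls"] == (96, 4, 0)
        assert sum(f["cases"]) == sum(f["controls"]) == 100


class TestFisher2x3:
    def test_modal_table_p_is_one(self):
        t = GenotypeCountTable(cases=(2, 2, 2), controls=(2, 2, 2))
        assert fisher_exact_2x3(t).p_value == pytest.approx(1.0)

    def test_against_enumeration_oracle(self):
        t = GenotypeCountTable(cases=(3, 1, 0), controls=(0, 1, 3))
        expected = fisher_2xk_oracle(t.cases, t.controls)
        assert fisher_exact_2x3(t).p_value == pytest.approx(expected, rel=1e-9)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.lists(st.integers(0, 6), min_size=6, max_size=6))
    def test_matches_oracle_on_random_small_tables(self, cells):
        cases, controls = tuple(cells[:3]), tuple(cells[3:])
        if sum(cases) == 0 or sum(controls) == 0:
            return
        t = GenotypeCountTable(cases=cases, controls=controls)
        assert fisher_exact_2x3(t).p_value == pytest.approx(
            fisher_2xk_oracle(cases, controls), rel=1e-9)

    def test_zero_column_reduces_to_2x2(self):
        """With one genotype class absent the 2x3 p equals the 2x2 Fisher p
        (independent route: scipy's minlike two-sided 2x2 test)."""
        t = GenotypeCountTable(cases=(12, 5, 0), controls=(7, 11, 0))
        ours = fisher_exact_2x3(t).p_value
        scipy_p = sps.fisher_exact([[12, 5], [7, 11]], alternative="two-sided")[1]
        assert ours == pytest.approx(scipy_p, rel=1e-9)

    def test_single_nonzero_column_degenerate(self):
        t = GenotypeCountTable(cases=(5, 0, 0), controls=(9, 0, 0))
        r = fisher_exact_2x3(t)
        assert r.p_value == 1.0 and "degenerate" in r.flags

    def test_cohort_scale_runs(self):
        t = GenotypeCountTable(cases=(70, 35, 4), controls=(90, 20, 1))
        p = fisher_exact_2x3(t).p_value
        assert 0 < p < 1


class TestFisherAllele2x2:
    def test_equal_frequencies_give_p_one(self):
        t = GenotypeCountTable(cases=(10, 20, 10), controls=(10, 20, 10))
        assert fisher_exact_allele_2x2(t).p_value == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        # case alleles (10,0) vs control alleles (0,10): the only tables no
        # more probable than observed are the two extremes, each weight 1
        t = GenotypeCountTable(cases=(5, 0, 0), controls=(0, 0, 5))
        expected = 2 / math.comb(20, 10)
        assert fisher_exact_allele_2x2(t).p_value == pytest.approx(expected, rel=1e-9)

    def test_matches_scipy_two_sided(self):
        t = GenotypeCountTable(cases=(60, 40, 9), controls=(80, 28, 3))
        (ca, cb), (ka, kb) = t.allele_counts()
        scipy_p = sps.fisher_exact([[ca, cb], [ka, kb]], alternative="two-sided")[1]
        assert fisher_exact_allele_2x2(t).p_value == pytest.approx(scipy_p, rel=1e-9)


def exact_permutation_p(table, scores=(0.0, 1.0, 2.0)):
    """Exact ties-included permutation tail of the trend statistic, by full
    enumeration of the fixed-margin null (independent oracle)."""
    cols = np.array(table.column_totals)
    m = min(table.n_cases, table.n_controls)
    rows = [(a0, a1, m - a0 - a1)
            for a0 in range(min(cols[0], m) + 1)
            for a1 in range(min(cols[1], m - a0) + 1)
            if 0 <= m - a0 - a1 <= cols[2]]
    rows = np.array(rows)
    pmf = multivariate_hypergeom.pmf(rows, cols, m)
    s = np.asarray(scores)
    null_stats = _trend_statistic(rows, cols, s)
    obs = _trend_statistic(np.array(table.cases)[None, :], cols, s)[0]
    return float(pmf[null_stats >= obs - 1e-12].sum())


class TestArmitageTrend:
    def test_identical_distributions_give_zero_statistic(self):
        t = GenotypeCountTable(cases=(30, 20, 10), controls=(30, 20, 10))
        r = armitage_trend(t)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_monte_carlo_floor(self):
        t = GenotypeCountTable(cases=(0, 0, 20), controls=(20, 0, 0))
        r = armitage_trend(t, mode="monte_carlo", reps=99, seed=1)
        assert r.p_value >= 1 / 100

    def test_zero_score_variance_flagged(self):
        t = GenotypeCountTable(cases=(0, 10, 0), controls=(0, 12, 0))
        r = armitage_trend(t)
        assert r.p_value == 1.0 and "zero_score_variance" in r.flags

    def test_monte_carlo_matches_exact_permutation_null(self):
        """The MC estimator converges on the exact ties-included permutation
        tail (its own defining limit), within Monte-Carlo error."""
        t = GenotypeCountTable(cases=(60, 40, 9), controls=(80, 28, 3))
        exact = exact_permutation_p(t)
        reps = 40_000
        mc = armitage_trend(t, mode="monte_carlo", reps=reps, seed=5).p_value
        se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(mc - exact) <= 3 * se + 1 / (reps + 1)

    def test_label_swap_with_score_reversal_is_invariant(self):
        """Permutation p is bit-identical (same seed) when cases and controls
        are swapped and the genotype scores reversed."""
        t = GenotypeCountTable(cases=(50, 40, 19), controls=(70, 28, 13))
        swapped = GenotypeCountTable(cases=t.controls, controls=t.cases)
        a = armitage_trend(t, scores=(0, 1, 2), mode="monte_carlo", reps=5000, seed=9)
        b = armitage_trend(swapped, scores=(2, 1, 0), mode="monte_carlo", reps=5000, seed=9)
        assert a.p_value == b.p_value
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_asymptotic_statistic_value(self):
        # classical 1-df trend chi-square, hand-checkable via its closed form
        t = GenotypeCountTable(cases=(10, 20, 30), controls=(30, 20, 10))
        r = armitage_trend(t)
        n, r1 = 120, 60
        tt, s1, s2 = 80.0, 120.0, 200.0
        expected = n * (n * tt - r1 * s1) ** 2 / (r1 * (n - r1) * (n * s2 - s1 ** 2))
        assert r.statistic == pytest.approx(expected, rel=1e-12)
        assert r.p_value == pytest.approx(sps.chi2.sf(expected, 1), rel=1e-9)

    def test_invalid_modes_and_reps(self):
        t = GenotypeCountTable(cases=(5, 5, 5), controls=(5, 5, 5))
        with pytest.raises(ValueError):
            armitage_trend(t, mode="bootstrap")
        with pytest.raises(ValueError):
            armitage_trend(t, mode="monte_carlo", reps=0)
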