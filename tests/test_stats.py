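"""Unit and property tests for the statistical kernel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pollentx.stats import (
    ContingencyTable2x2,
    auxiliary_test,
    benjamini_hochberg,
    binomial_deviance,
    fisher_exact_2x2,
    kendall_tau_b,
    linear_regression,
    pearson_dispersion,
    quasibinomial_test,
)

from oracles import bh_definitional, fisher_p_enumeration, kendall_tau_b_pairs


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected_3sf",
        [
            ((6, 6, 28, 0), 0.000241),   # fertilization-outcome comparison
            ((6, 6, 1, 19), 0.00572),    # high- vs low-expression defect split
        ],
    )
    def test_published_two_sided_p(self, table, expected_3sf):
        res = fisher_exact_2x2(ContingencyTable2x2(*table))
        assert res.p_value == pytest.approx(expected_3sf, rel=5e-3)

    def test_small_table_exact_fraction(self):
        # all margins fixed at 2: three tables, observed has prob 1/6 on
        # each diagonal extreme; two-sided p = 1/6 + 1/6 = 1/3
        res = fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2))
        assert res.p_value == pytest.approx(1 / 3)

    def test_one_sided_class_comparisons(self):
        # defect proportions among gene classes: one-sided tests reproduce
        # the printed 0.500 / 0.125 / 0.374 trio
        assert fisher_exact_2x2(ContingencyTable2x2(0, 10, 1, 9), "less").p_value == pytest.approx(0.500, abs=5e-4)
        assert fisher_exact_2x2(ContingencyTable2x2(0, 10, 7, 25), "less").p_value == pytest.approx(0.125, abs=5e-4)
        assert fisher_exact_2x2(ContingencyTable2x2(7, 25, 1, 9), "greater").p_value == pytest.approx(0.374, abs=5e-4)

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 5))
        assert res.p_value == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(120):
            cells = rng.integers(0, 16, size=4)
            if cells.sum() == 0:
                continue
            a, b, c, d = (int(v) for v in cells)
            for alt in ("two-sided", "less", "greater"):
                got = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d), alt).p_value
                want = fisher_p_enumeration(a, b, c, d, alt)
                assert got == pytest.approx(want, abs=1e-9), (a, b, c, d, alt)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_exact_2x2(ContingencyTable2x2(1, 2, 3, 4), "both")


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p_in, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([], []),
        ],
    )
    def test_examples(self, p_in, expected):
        np.testing.assert_allclose(benjamini_hochberg(p_in), expected)

    def test_identical_values_unchanged(self):
        p = np.full(7, 0.042)
        np.testing.assert_allclose(benjamini_hochberg(p), p)

    def test_nan_passthrough_excluded_from_m(self):
        out = benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # m = 2, not 3
        np.testing.assert_allclose(out[[0, 2]], bh_definitional([0.01, 0.04]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_definition_never_decreases(self, p):
        out = benjamini_hochberg(p)
        np.testing.assert_allclose(out, bh_definitional(p), atol=1e-12)
        assert np.all(out >= np.asarray(p) - 1e-12)
        assert np.all(out <= 1.0 + 1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=25), st.randoms())
    def test_permutation_invariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        base = benjamini_hochberg(p)
        shuffled = benjamini_hochberg([p[i] for i in perm])
        np.testing.assert_allclose([base[i] for i in perm], shuffled, atol=1e-12)


class TestKendallTau:
    def test_perfect_monotone(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert kendall_tau_b([1, 2, 3, 4], [40, 30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_one_discordant_pair(self):
        assert kendall_tau_b([1, 2, 3], [1, 3, 2]).statistic == pytest.approx(1 / 3)

    def test_all_tied_flagged(self):
        res = kendall_tau_b([1, 1, 1], [1, 2, 3])
        assert np.isnan(res.statistic) and "all_tied" in res.flags

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.integers(0, 6, n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            got = kendall_tau_b(x, y).statistic
            assert got == pytest.approx(kendall_tau_b_pairs(x, y), abs=1e-12)

    def test_antisymmetric_under_y_reversal(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert kendall_tau_b(x, y).statistic == pytest.approx(-kendall_tau_b(x, -y).statistic)


class TestQuasiBinomial:
    def test_data_at_null(self):
        fit, res = quasibinomial_test([50, 50, 50], [100, 100, 100], 0.5)
        assert fit.fitted_rate == 0.5
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_phi_one_limit_equals_binomial_lrt(self):
        _, res = quasibinomial_test([40], [100], 0.5, phi_override=1.0)
        y, n = 40, 100
        dev = 2 * (y * np.log(y / (n * 0.5)) + (n - y) * np.log((n - y) / (n * 0.5)))
        assert res.p_value == pytest.approx(sps.chi2.sf(dev, 1), abs=1e-6)

    def test_pearson_dispersion_hand_computation(self):
        y = np.array([30.0, 60.0])
        n = np.array([100.0, 100.0])
        rate = 0.45  # pooled
        expected = ((30 - 45) ** 2 / (100 * 0.45 * 0.55) + (60 - 45) ** 2 / (100 * 0.45 * 0.55)) / 1
        assert pearson_dispersion(y, n, rate, 1) == pytest.approx(expected)
        fit, _ = quasibinomial_test([30, 60], [100, 100], 0.5)
        assert fit.dispersion_phi == pytest.approx(expected)

    def test_boundary_fit_flagged(self):
        fit, res = quasibinomial_test([0, 0, 0], [50, 50, 50], 0.5)
        assert fit.fitted_rate == 0.0 and fit.boundary
        assert "boundary_fit" in res.flags
        assert 0.0 <= res.p_value <= 1.0

    def test_single_ear_requires_phi_override(self):
        with pytest.raises(ValueError, match="phi_override"):
            quasibinomial_test([40], [100], 0.5)

    def test_deviance_nesting(self, rng):
        for _ in range(20):
            n = rng.integers(50, 500, size=4)
            y = rng.binomial(n, 0.4)
            fit, _ = quasibinomial_test(list(y), list(n), 0.5)
            assert fit.null_deviance >= fit.deviance - 1e-9


class TestLinearRegression:
    def test_exact_fit(self):
        x = np.arange(5.0)
        res = linear_regression(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r2_adjusted == pytest.approx(1.0)

    def test_hand_computed_ols(self):
        res = linear_regression([1, 2, 3, 4], [1, 2, 2, 3])
        assert res.slope == pytest.approx(0.6)
        assert res.r2_adjusted == pytest.approx(1 - (1 - 0.9) * 3 / 2)

    def test_zero_variance_x_errors(self):
        with pytest.raises(ValueError):
            linear_regression([1, 1, 1], [1, 2, 3])

    def test_null_p_roughly_uniform(self, rng):
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            hits += linear_regression(x, y).slope_p < 0.05
        # binomial(300, .05): mean 15, sd ~3.8
        assert abs(hits - 0.05 * n_sim) < 4 * np.sqrt(n_sim * 0.05 * 0.95)


class TestAuxiliary:
    def test_welch_identical_samples(self):
        res = auxiliary_test("welch_t", a=[1.0, 2.0, 3.0], b=[1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_exact_binomial_at_mode(self):
        assert auxiliary_test("exact_binomial", k=5, n=10, p0=0.5).p_value == 1.0

    def test_exact_binomial_extreme_tail(self):
        res = auxiliary_test("exact_binomial", k=10, n=10, p0=0.5)
        assert res.p_value == pytest.approx(2 * 0.5**10)

    def test_two_proportion_cc_matches_R_prop_test(self):
        # frozen from R: prop.test(c(30,20), c(100,100))
        res = auxiliary_test("two_proportion_cc", successes=[30, 20], totals=[100, 100])
        assert res.statistic == pytest.approx(2.16, abs=1e-9)
        assert res.p_value == pytest.approx(0.1416446903, abs=1e-9)

    def test_unknown_mode_and_small_n(self):
        with pytest.raises(ValueError):
            auxiliary_test("median_test")
        with pytest.raises(ValueError):
            auxiliary_test("welch_t", a=[1.0], b=[1.0, 2.0])
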