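import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ultravar.reml import VarianceComponents
from ultravar.stats import (
    PartitionSummary,
    bartlett_homogeneity,
    dispersion_range_over_mean,
    heritability,
    residuals_within_technician,
    se_genetic_correlation,
    spearman_ebv_correlation,
    variance_percentages,
)


class TestHeritability:
    @pytest.mark.parametrize(
        "sa, se, expected",
        [(16.87, 35.06, 0.3249), (0.52, 0.26, 0.6667), (0.0, 1.0, 0.0)],
    )
    def test_values(self, sa, se, expected):
        assert heritability(sa, se) == pytest.approx(expected, abs=5e-5)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)


class TestVariancePercentages:
    def test_reference_row(self):
        # technician 53.98, CG 124.13, additive 16.87, residual 35.06
        p = variance_percentages(VarianceComponents(53.98, 124.13, 16.87, 35.06))
        assert tuple(int(round(x)) for x in p) == (23, 54, 7, 15)

    def test_equal_components(self):
        p = variance_percentages(VarianceComponents(2.0, 2.0, 2.0, 2.0))
        np.testing.assert_allclose(p, [25, 25, 25, 25])

    def test_sum_to_100(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vc = VarianceComponents(*rng.uniform(0.01, 10, size=4))
            assert variance_percentages(vc).sum() == pytest.approx(100.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            variance_percentages(VarianceComponents(0, 0, 0, 0))


class TestDispersion:
    def test_lma_additive_across_labs(self):
        assert dispersion_range_over_mean([16.87, 16.65, 17.41]) == pytest.approx(
            4.48, abs=0.005
        )

    def test_imf_residual_across_labs(self):
        assert dispersion_range_over_mean([0.27, 0.13, 0.32]) == pytest.approx(
            79.2, abs=0.05
        )

    def test_identical_values(self):
        assert dispersion_range_over_mean([3.0, 3.0, 3.0]) == 0.0

    def test_nonpositive_mean_errors(self):
        with pytest.raises(ValueError):
            dispersion_range_over_mean([-1.0, 1.0])


class TestResidualsWithinTechnician:
    def test_cg_mean_centering(self):
        df = pd.DataFrame(
            {"value": [4.0, 6.0], "cg": ["c", "c"], "technician": ["t", "t"]}
        )
        groups, dropped = residuals_within_technician(df)
        np.testing.assert_allclose(np.sort(groups["t"]), [-1.0, 1.0])
        assert dropped == 0

    def test_constant_cgs_give_zero(self):
        df = pd.DataFrame(
            {
                "value": [5.0] * 4 + [9.0] * 4,
                "cg": ["a"] * 4 + ["b"] * 4,
                "technician": ["t1"] * 4 + ["t2"] * 4,
            }
        )
        groups, _ = residuals_within_technician(df)
        for g in groups.values():
            np.testing.assert_allclose(g, 0.0)

    def test_singletons_dropped_and_counts_partition(self):
        df = pd.DataFrame(
            {
                "value": [1.0, 2.0, 3.0, 4.0, 5.0],
                "cg": ["a", "a", "b", "b", "solo"],
                "technician": ["t1", "t1", "t2", "t2", "t2"],
            }
        )
        groups, dropped = residuals_within_technician(df)
        assert dropped == 1
        assert sum(len(g) for g in groups.values()) == 4


class TestBartlett:
    def test_equal_variances_statistic_zero(self):
        g = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([4.0, 5.0, 6.0])}
        res = bartlett_homogeneity(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_formula(self):
        # k=2, n1=n2=5, s1^2=1, s2^2=4: classical statistic with Box correction
        n1 = n2 = 5
        s1, s2 = 1.0, 4.0
        sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
        T = (n1 + n2 - 2) * np.log(sp2) - (n1 - 1) * np.log(s1) - (n2 - 1) * np.log(s2)
        C = 1 + (1 / (n1 - 1) + 1 / (n2 - 1) - 1 / (n1 + n2 - 2)) / (3 * (2 - 1))
        expected = T / C
        g1 = np.array([0.0, 1.0, 2.0, 3.0, 4.0])  # variance 2.5
        g1 = (g1 - g1.mean()) / np.sqrt(2.5)  # variance exactly 1
        g2 = g1 * 2.0  # variance exactly 4
        res = bartlett_homogeneity({"a": g1, "b": g2})
        assert res.statistic == pytest.approx(expected, rel=1e-10)
        assert res.df == 1

    def test_zero_variance_group_flagged(self):
        g = {"a": np.array([1.0, 1.0, 1.0]), "b": np.array([1.0, 2.0, 3.0])}
        res = bartlett_homogeneity(g)
        assert np.isinf(res.statistic) and res.p_value == 0.0
        assert res.zero_variance_groups == ["a"]

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            bartlett_homogeneity({"a": np.array([1.0, 2.0])})


class TestSeGeneticCorrelation:
    def test_reduces_to_classical_at_unit_accuracy(self):
        import sympy

        rg, N = sympy.symbols("rg N", positive=True)
        expr = sympy.sqrt(
            (1 + (1 + sympy.Rational(1, 2) + sympy.Rational(1, 2) - 2 - 2) * rg**2 + rg**4)
            / (N - 1)
        )
        classical = (1 - rg**2) / sympy.sqrt(N - 1)
        assert sympy.simplify(expr**2 - classical**2) == 0
        for r in (0.0, 0.3, 0.9):
            assert se_genetic_correlation(r, 1.0, 1.0, 101) == pytest.approx(
                (1 - r**2) / 10.0
            )

    def test_degenerate_limit(self):
        assert se_genetic_correlation(1.0, 1.0, 1.0, 50) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        assert se_genetic_correlation(0.0, 0.8, 0.8, 401) == pytest.approx(
            np.sqrt((1 / 0.4096) / 400), rel=1e-12
        )
        assert se_genetic_correlation(0.0, 0.8, 0.8, 401) == pytest.approx(0.0781, abs=5e-5)

    def test_monotone_in_N_and_accuracy(self):
        rg = 0.7
        ses_N = [se_genetic_correlation(rg, 0.6, 0.6, N) for N in (10, 50, 200, 1000)]
        assert all(a > b for a, b in zip(ses_N, ses_N[1:]))
        ses_r = [se_genetic_correlation(rg, r, 0.6, 100) for r in (0.3, 0.5, 0.7, 0.95)]
        assert all(a > b for a, b in zip(ses_r, ses_r[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            se_genetic_correlation(0.5, 0.0, 0.8, 100)
        with pytest.raises(ValueError):
            se_genetic_correlation(0.5, 0.8, 0.8, 1)


class TestSpearman:
    def test_identical_and_reversed(self):
        e1 = {f"s{i}": float(i) for i in range(6)}
        e2 = {f"s{i}": float(-i) for i in range(6)}
        assert spearman_ebv_correlation(e1, e1) == (pytest.approx(1.0), 6)
        rho, n = spearman_ebv_correlation(e1, e2)
        assert rho == pytest.approx(-1.0) and n == 6

    def test_tie_matches_rank_then_pearson(self):
        e1 = {"a": 1.0, "b": 2.0, "c": 2.0, "d": 4.0, "e": 5.0}
        e2 = {"a": 2.0, "b": 1.0, "c": 4.0, "d": 3.0, "e": 5.0}
        r1 = pd.Series(e1).rank()
        r2 = pd.Series(e2).rank()
        expected = np.corrcoef(r1, r2)[0, 1]
        rho, _ = spearman_ebv_correlation(e1, e2)
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_intersection_only(self):
        e1 = {"a": 1.0, "b": 2.0, "c": 3.0, "x": 9.0}
        e2 = {"a": 1.0, "b": 2.0, "c": 3.0, "y": -9.0}
        rho, n = spearman_ebv_correlation(e1, e2)
        assert n == 3 and rho == pytest.approx(1.0)

    def test_too_few_common(self):
        with pytest.raises(ValueError, match="common sires"):
            spearman_ebv_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


@settings(max_examples=50, deadline=None)
@given(
    st.tuples(
        st.floats(0.01, 100),
        st.floats(0.01, 100),
        st.floats(0.01, 100),
        st.floats(0.01, 100),
    )
)
def test_h2_at_least_additive_percentage(vals):
    """With technician/CG variance present the h2 denominator is smaller,
    so h2 always exceeds the additive share of total phenotypic variance."""
    vc = VarianceComponents(*vals)
    pct_additive = variance_percentages(vc)[2] / 100.0
    assert heritability(vc.sigma2_a, vc.sigma2_e) >= pct_additive - 1e-12


def test_partition_summary_from_fit():
    vc = VarianceComponents(53.98, 124.13, 16.87, 35.06)
    cov = np.diag([4.0, 9.0, 1.0, 0.5])
    ps = PartitionSummary.from_fit(vc, cov)
    assert ps.percents.sum() == pytest.approx(100.0)
    assert ps.h2 == pytest.approx(0.3249, abs=5e-5)
    assert np.all(ps.percent_se >= 0) and ps.h2_se > 0
    ps_nocov = PartitionSummary.from_fit(vc, None)
    assert np.all(np.isnan(ps_nocov.percent_se))
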