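"""Exact categorical statistics and the family-then-pairwise policy."""

import numpy as np
import pytest
import scipy.stats as sps
from helpers import barnard_oracle

from mnlamina.stats import (
    ContingencyTable2x2,
    PowerSpec,
    barnard_exact,
    chi_square_family,
    chisq_power,
    hierarchical_compare,
    phi_coefficient,
    spearman_rho,
)


class TestBarnardExact:
    def test_balanced_table_p_one(self):
        assert barnard_exact(ContingencyTable2x2(1, 1, 1, 1)).p_value == 1.0

    def test_small_tables_match_enumeration_oracle(self):
        """Spot-check a diverse set of small tables against the
        independent full-enumeration oracle (exhaustive sweep lives in
        the acceptance suite)."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            n1, n2 = rng.integers(1, 8, 2)
            x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            t = ContingencyTable2x2(int(x1), int(n1 - x1),
                                    int(x2), int(n2 - x2))
            assert barnard_exact(t).p_value == pytest.approx(
                barnard_oracle(*[t.n11, t.n12, t.n21, t.n22]), abs=1e-10)

    def test_validation_table_highly_significant(self):
        """The marker-validation table (183/10 vs 9/107) is significant
        far beyond the 0.0001 level."""
        t = ContingencyTable2x2(183, 10, 9, 107)
        assert barnard_exact(t).p_value < 1e-4

    def test_agrees_with_scipy_cross_check(self):
        for counts in [(7, 12, 8, 3), (10, 5, 3, 12), (2, 7, 6, 2)]:
            t = ContingencyTable2x2(*counts)
            ours = barnard_exact(t).p_value
            # scipy's nuisance grid is far coarser (n=32), so agreement
            # is only to a few 1e-3
            ref = sps.barnard_exact(t.as_array()).pvalue
            assert ours == pytest.approx(ref, abs=2e-3)

    def test_zero_row_total_rejected(self):
        with pytest.raises(ValueError):
            barnard_exact(ContingencyTable2x2(0, 0, 3, 4))

    def test_one_sided_not_larger_than_two_sided(self):
        t = ContingencyTable2x2(9, 2, 3, 8)
        assert barnard_exact(t, "one-sided").p_value <= \
            barnard_exact(t, "two-sided").p_value + 1e-12


class TestPhiCoefficient:
    def test_validation_tables_reproduce_printed_values(self):
        assert phi_coefficient(ContingencyTable2x2(183, 10, 9, 107)) == \
            pytest.approx(0.87, abs=0.005)
        assert phi_coefficient(ContingencyTable2x2(18, 119, 115, 2)) == \
            pytest.approx(-0.85, abs=0.005)

    @pytest.mark.parametrize("n,m", [(1, 1), (5, 3), (40, 17)])
    def test_perfect_association(self, n, m):
        assert phi_coefficient(ContingencyTable2x2(n, 0, 0, m)) == \
            pytest.approx(1.0)

    def test_swap_symmetries(self):
        t = ContingencyTable2x2(20, 5, 7, 18)
        base = phi_coefficient(t)
        rows_swapped = ContingencyTable2x2(7, 18, 20, 5)
        both_swapped = ContingencyTable2x2(18, 7, 5, 20)
        assert phi_coefficient(rows_swapped) == pytest.approx(-base)
        assert phi_coefficient(both_swapped) == pytest.approx(base)

    def test_zero_marginal_undefined(self):
        with pytest.raises(ValueError):
            phi_coefficient(ContingencyTable2x2(3, 0, 4, 0))


class TestChiSquareFamily:
    def test_homogeneous_table(self):
        res = chi_square_family([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        """[[20,5],[5,20]]: all expected counts are 12.5, each cell
        contributes 7.5^2/12.5 = 4.5, statistic = 18."""
        res = chi_square_family([[20, 5], [5, 20]])
        assert res.statistic == pytest.approx(18.0)
        assert res.df == 1

    def test_zero_cell_flagged_invalid(self):
        res = chi_square_family([[0, 10], [5, 5]])
        assert any("zero-cell" in f for f in res.flags)

    def test_small_expected_counts_flagged(self):
        res = chi_square_family([[2, 3], [3, 2]])
        assert any("expected-count" in f for f in res.flags)


class TestHierarchicalCompare:
    def test_identical_count_groups_no_pairwise(self):
        res = hierarchical_compare([[10, 10], [10, 10], [10, 10]])
        assert res["family"].p_value == pytest.approx(1.0)
        assert res["pairwise"] == []

    def test_extreme_pair_has_smallest_adjusted_p(self):
        """With class proportions (0.2, 0.5, 0.8, 0.5, 0.5) at n = 200,
        the family test rejects and the 0.2-vs-0.8 Barnard pair is the
        most significant, across seeds."""
        from mnlamina.synthetic_data import generate_population

        ps = {"a": 0.2, "b": 0.5, "c": 0.8, "d": 0.5, "e": 0.5}
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            truth, _ = generate_population({k: 200 for k in ps}, ps, seed=seed)
            counts = []
            for cls in ps:
                sub = truth[truth["class"] == cls]
                k = int((sub["rupture_state"] == "intact").sum())
                counts.append([k, 200 - k])
            res = hierarchical_compare(np.array(counts))
            if not res["pairwise"]:
                continue
            best = min(res["pairwise"], key=lambda r: r.p_value)
            if best.extra["pair"] == (0, 2):
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_heavy_tailed_groups_take_kruskal_branch(self):
        rng = np.random.default_rng(7)
        groups = [rng.standard_cauchy(30) for _ in range(3)]
        res = hierarchical_compare(groups, kind="continuous")
        assert res["branch"] == "kruskal-wallis"

    def test_normal_groups_take_anova_branch(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1.0, 40) for m in (0.0, 0.1, 5.0)]
        res = hierarchical_compare(groups, kind="continuous")
        assert res["branch"] == "anova"
        assert res["pairwise"]  # clearly separated means

    def test_small_continuous_group_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_compare([[1.0, 2.0], [1.0, 2.0, 3.0]],
                                 kind="continuous")


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x ** 3) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestChisqPower:
    def test_null_effect_gives_alpha(self):
        assert chisq_power(PowerSpec(0.0, 100, 1)) == pytest.approx(0.05)

    def test_monotone_in_sample_size(self):
        powers = [chisq_power(PowerSpec(0.3, n, 1)) for n in
                  (20, 50, 100, 400, 2000)]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_matches_monte_carlo_simulation(self):
        """w = 0.15, N = 400, df = 1: simulate the two-cell goodness-of-fit
        chi-square under the alternative and compare rejection rates (the
        sample size is large enough for the noncentral asymptotics to
        hold to ~1%)."""
        spec = PowerSpec(0.15, 400, 1)
        analytic = chisq_power(spec)
        rng = np.random.default_rng(42)
        p0 = np.array([0.5, 0.5])
        # two-cell probabilities at Cohen's w: w = 2*delta for df = 1
        delta = spec.effect_w / 2.0
        p1 = np.array([0.5 + delta, 0.5 - delta])
        crit = sps.chi2.ppf(0.95, 1)
        counts = rng.multinomial(spec.N_total, p1, size=100_000)
        expected = spec.N_total * p0
        stat = ((counts - expected) ** 2 / expected).sum(axis=1)
        assert analytic == pytest.approx((stat > crit).mean(), abs=0.01)
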