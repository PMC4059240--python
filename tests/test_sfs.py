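"""SFS construction, shift tests, permutation tests, ANOVA, G-tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonsfs.neutral import NeutralModelParams
from codonsfs.sfs import (
    SFS,
    asm_randomized_permutation_test,
    compare_slopes,
    g_test,
    permutation_test,
    sequential_bonferroni,
    shift_tests,
    slope_d_on_dpref,
    sum_product_statistic,
    two_way_anova,
)


class TestSFS:
    def test_counts_and_mean(self):
        sfs = SFS.from_d([1, 1, 5], k=11)
        assert sfs.counts[0] == 2 and sfs.counts[4] == 1
        assert sfs.mean_d == pytest.approx(7 / 3)

    def test_singleton_exclusion_drops_both_tails(self):
        sfs = SFS.from_d([1, 2, 5, 10, 10], k=11)
        ns = sfs.excluding_singletons()
        assert ns.n_sites == 2
        assert ns.mean_d == pytest.approx(3.5)

    def test_out_of_range_d_rejected(self):
        with pytest.raises(ValueError):
            SFS.from_d([0, 3], k=11)
        with pytest.raises(ValueError):
            SFS.from_d([11], k=11)


def brute_force_u(a, b):
    """Mann-Whitney U of a over b by direct pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            u += (x > y) + 0.5 * (x == y)
    return u


class TestShiftTests:
    def test_identical_groups_p_near_half(self, rng):
        x = rng.integers(1, 11, size=400).astype(float)
        t_res, u_res = shift_tests(x, x.copy())
        assert t_res.p_value == pytest.approx(0.5, abs=0.02)
        assert u_res.p_value == pytest.approx(0.5, abs=0.02)

    def test_complete_separation_significant(self):
        t_res, u_res = shift_tests([5, 5, 5], [1, 1, 1])
        assert t_res.p_value < 0.05
        assert u_res.p_value < 0.05

    def test_u_statistic_matches_pair_counting(self, rng):
        a = rng.integers(1, 8, size=9)
        b = rng.integers(1, 8, size=7)
        _, u_res = shift_tests(a, b)
        assert u_res.statistic == pytest.approx(brute_force_u(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            shift_tests([], [1, 2])


class TestPermutationTest:
    def test_constant_dpref_gives_p_one(self):
        res = permutation_test([1, 2, 3], [0.5, 0.5, 0.5], replicates=100, seed=0)
        assert res.p_value == 1.0
        assert "invariant" in res.note

    def test_exhaustive_enumeration_matches_monte_carlo(self, rng):
        d = np.array([1.0, 2.0, 4.0, 7.0, 9.0, 10.0])
        dp = rng.normal(size=6)
        t_obs = sum_product_statistic(d, dp)
        perms = list(itertools.permutations(d))
        p_exact = sum(np.dot(p, dp) > t_obs for p in perms) / len(perms)
        n_rep = 20_000
        res = permutation_test(d, dp, replicates=n_rep, seed=7)
        se = math.sqrt(p_exact * (1 - p_exact) / n_rep)
        assert abs(res.p_value - p_exact) <= 3 * se + 1e-12

    def test_planted_positive_coupling_detected(self, rng):
        dp = rng.normal(size=50)
        d = np.clip(np.round(3 + 2.5 * dp + rng.normal(0, 0.5, 50)), 1, 10)
        res = permutation_test(d, dp, replicates=5000, seed=3)
        assert res.p_value < 0.001

    def test_statistic_negates_under_polarity_flip(self, rng):
        d = rng.integers(1, 11, size=30).astype(float)
        dp = rng.normal(size=30)
        assert sum_product_statistic(d, -dp) == pytest.approx(
            -sum_product_statistic(d, dp)
        )

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1], [0.2], replicates=10, seed=0)


class TestAsmPermutationTest:
    PARAMS = NeutralModelParams(k=11, theta=0.0222, div=0.0763)

    def test_vanishing_branch_length_reduces_to_plain_test(self, rng):
        # b -> 0+: flip probabilities vanish and every draw equals parsimony
        params = NeutralModelParams(k=11, theta=0.0222, div=0.0222 * 10 / 11 + 1e-9)
        d = rng.integers(1, 11, size=40)
        dp = rng.normal(size=40)
        plain = permutation_test(d.astype(float), dp, replicates=4000, seed=11)
        asm = asm_randomized_permutation_test(
            d, dp, params, replicates=4000, assignment_draws=4, seed=11
        )
        assert abs(asm.p_value - plain.p_value) < 0.05

    def test_flip_probability_consistent_with_posterior_odds(self):
        from codonsfs.neutral import asm_probability, posterior_odds

        odds = posterior_odds(10, self.PARAMS)
        assert odds == pytest.approx((11 - 10) / 10 / self.PARAMS.b)
        assert asm_probability(10, self.PARAMS) == pytest.approx(1 / (1 + odds))

    def test_planted_selection_survives_asm_correction(self, rng):
        dp = rng.normal(0, 0.7, size=300)
        d = np.clip(np.round(3 + 2.0 * dp + rng.normal(0, 1.0, 300)), 1, 10).astype(int)
        res = asm_randomized_permutation_test(
            d, dp, self.PARAMS, replicates=10_000, assignment_draws=10, seed=5
        )
        assert res.p_value < 0.001

    def test_negative_branch_length_rejected(self):
        bad = NeutralModelParams(k=11, theta=0.1, div=0.01)
        with pytest.raises(ValueError):
            asm_randomized_permutation_test(
                [1, 2], [0.1, -0.1], bad, replicates=10, seed=0
            )


class TestSlopes:
    def test_perfect_line(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        fit = slope_d_on_dpref(2 * x + 3, x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            slope_d_on_dpref([1, 2, 3], [0.5, 0.5, 0.5])

    def test_matches_covariance_ratio(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        fit = slope_d_on_dpref(y, x)
        assert fit.slope == pytest.approx(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))

    def test_identical_groups_not_significant(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(0, 1, 200)
        out = compare_slopes({"a": (y, x), "b": (y.copy(), x.copy())})
        assert out["p_value"].iloc[0] > 0.4

    def test_planted_slope_difference_detected(self, rng):
        n = 500
        xa, xb = rng.normal(size=n), rng.normal(size=n)
        ya = 0.2 * xa + rng.normal(0, 2, n)
        yb = 0.7 * xb + rng.normal(0, 2, n)
        out = compare_slopes({"low": (ya, xa), "high": (yb, xb)}, one_tailed=True)
        assert out["p_value"].iloc[0] < 0.05

    def test_invalid_group_omitted(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        groups = {
            "ok1": (y, x),
            "ok2": (y + 0.1, x),
            "degenerate": (np.ones(5), np.ones(5)),
        }
        out = compare_slopes(groups)
        assert set(out["group_a"]) | set(out["group_b"]) == {"ok1", "ok2"}


class TestTwoWayAnova:
    def test_equal_cell_means_zero_effect_ss(self):
        a = ["x"] * 8 + ["y"] * 8
        b = (["u"] * 4 + ["v"] * 4) * 2
        y = [5.0, 6.0, 4.0, 5.0] * 4  # identical within each cell pattern
        table = two_way_anova(y, a, b)
        assert table.loc["site_type", "SS"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["direction", "SS"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["interaction", "SS"] == pytest.approx(0.0, abs=1e-10)

    def test_balanced_design_matches_hand_decomposition(self):
        # 2x2 with 2 obs/cell; cell means 1, 3, 2, 6
        y = np.array([0.5, 1.5, 2.5, 3.5, 1.5, 2.5, 5.5, 6.5])
        a = ["a1"] * 4 + ["a2"] * 4
        b = ["b1", "b1", "b2", "b2"] * 2
        table = two_way_anova(y, a, b)
        n = 2
        grand = y.mean()
        mean_a = {"a1": y[:4].mean(), "a2": y[4:].mean()}
        mean_b = {"b1": y[[0, 1, 4, 5]].mean(), "b2": y[[2, 3, 6, 7]].mean()}
        ss_a = sum(2 * n * (m - grand) ** 2 for m in mean_a.values())
        ss_b = sum(2 * n * (m - grand) ** 2 for m in mean_b.values())
        cells = {(x, z): y[[i for i in range(8) if a[i] == x and b[i] == z]].mean()
                 for x in mean_a for z in mean_b}
        ss_cells = sum(n * (m - grand) ** 2 for m in cells.values())
        ss_ab = ss_cells - ss_a - ss_b
        assert table.loc["site_type", "SS"] == pytest.approx(ss_a)
        assert table.loc["direction", "SS"] == pytest.approx(ss_b)
        assert table.loc["interaction", "SS"] == pytest.approx(ss_ab)
        # full decomposition on the balanced design
        ss_total = ((y - grand) ** 2).sum()
        assert table["SS"].sum() == pytest.approx(ss_total)

    def test_planted_interaction_recovered(self, rng):
        n = 300
        rows = []
        for site_type in ("codon", "intron"):
            for direction, base in (("T>C", 1.0), ("C>T", 0.0)):
                shift = base * (2.0 if site_type == "codon" else 0.8)
                rows.append(
                    pd.DataFrame(
                        {
                            "y": rng.normal(2.5 + shift, 1.5, n),
                            "a": site_type,
                            "b": direction,
                        }
                    )
                )
        df = pd.concat(rows)
        table = two_way_anova(df["y"], df["a"], df["b"])
        assert table.loc["direction", "p_value"] < 1e-6
        assert table.loc["interaction", "p_value"] < 1e-3

    def test_empty_cell_named_in_error(self):
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(
                [1.0, 2.0, 3.0], ["x", "x", "y"], ["u", "v", "u"]
            )


class TestGTest:
    def test_independent_table_gives_zero(self):
        res = g_test([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_scipy_log_likelihood_ratio(self, rng):
        table = rng.integers(5, 100, size=(3, 4))
        res = g_test(table)
        g_ref, p_ref, dof, _ = stats.chi2_contingency(
            table, correction=False, lambda_="log-likelihood"
        )
        assert res.statistic == pytest.approx(g_ref)
        assert res.p_value == pytest.approx(p_ref)
        assert f"df={dof}" == res.note

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            g_test([[0, 0], [3, 4]])


def test_sequential_bonferroni_known_example():
    p = [0.01, 0.04, 0.03, 0.005]
    adj = sequential_bonferroni(p)
    # Holm: sorted 0.005*4, 0.01*3, 0.03*2, 0.04*1 with running max
    assert adj == pytest.approx([0.03, 0.06, 0.06, 0.02])
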