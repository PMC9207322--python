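import itertools

import numpy as np
import pytest

from ergdwt.stats import (
    DegenerateInputError,
    chi_square_independence,
    kruskal_wallis,
    mann_whitney,
    mctp_tukey,
    pairwise_relative_effect,
    percentage_bend_correlation,
    relative_effects,
)


def enumerate_relative_effect(a, b):
    """Oracle: average over all |a|x|b| pairs of 1(a<b) + 0.5*1(a=b)."""
    total = 0.0
    for x in a:
        for y in b:
            total += 1.0 if x < y else (0.5 if x == y else 0.0)
    return total / (len(a) * len(b))


class TestRelativeEffects:
    def test_identical_samples_give_half(self):
        assert pairwise_relative_effect([3, 1, 2], [1, 2, 3]) == pytest.approx(0.5)

    def test_fully_separated(self):
        assert pairwise_relative_effect([1, 2], [3, 4]) == 1.0

    def test_ties_counted_half(self):
        assert pairwise_relative_effect([1, 3], [2, 3]) == pytest.approx(0.625)

    def test_matches_enumeration_on_ties_rich_samples(self, rng):
        """Placement estimator equals exhaustive pair enumeration for every
        group-size combination up to 6, on integer (ties-rich) data."""
        for na, nb in itertools.product(range(1, 7), repeat=2):
            for _ in range(5):
                a = rng.integers(0, 4, size=na).astype(float)
                b = rng.integers(0, 4, size=nb).astype(float)
                assert pairwise_relative_effect(a, b) == pytest.approx(
                    enumerate_relative_effect(a, b), abs=1e-12
                )

    def test_matrix_antisymmetry(self, rng):
        groups = {k: rng.integers(0, 5, size=6).astype(float) for k in "abc"}
        mat = relative_effects(groups)
        for i in "abc":
            for j in "abc":
                assert mat.loc[i, j] + mat.loc[j, i] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            relative_effects({"a": [1.0], "b": []})


class TestMctpTukey:
    def test_constant_samples_degenerate(self):
        res = mctp_tukey({"a": [2.0] * 5, "b": [2.0] * 5, "c": [2.0] * 5})
        assert res.degenerate
        np.testing.assert_array_equal(res.estimates, 0.5)
        np.testing.assert_array_equal(res.p_adjusted, 1.0)

    def test_well_separated_groups_all_rejected(self):
        res = mctp_tukey(
            {
                "g1": np.arange(1.0, 11.0),
                "g2": np.arange(101.0, 111.0),
                "g3": np.arange(201.0, 211.0),
            }
        )
        # boundary estimates shrunk by the half-count rule, not exactly 1
        assert np.all(res.estimates > 0.99)
        assert np.all(res.p_adjusted < 0.005)
        assert np.all(res.ci_lower <= res.estimates)
        assert np.all(res.ci_upper >= res.estimates)

    def test_two_group_p_matches_brunner_munzel(self, rng):
        from scipy.stats import brunnermunzel

        a, b = rng.normal(size=13), rng.normal(0.8, 1.3, size=17)
        res = mctp_tukey({"a": a, "b": b}, transformation="none")
        ref = brunnermunzel(a, b)
        assert res.p_adjusted[0] == pytest.approx(ref.pvalue, abs=2e-3)

    def test_estimates_in_unit_interval_and_cis_ordered(self, rng):
        groups = {k: rng.normal(loc, 1, 12) for k, loc in zip("abc", (0, 0.5, 1))}
        res = mctp_tukey(groups)
        assert np.all((res.estimates >= 0) & (res.estimates <= 1))
        assert np.all(res.ci_lower <= res.estimates)
        assert np.all(res.estimates <= res.ci_upper)
        assert np.all((res.ci_lower >= 0) & (res.ci_upper <= 1))

    def test_monotone_transform_invariance(self, rng):
        groups = {k: rng.normal(loc, 1, 15) for k, loc in zip("abc", (0, 1, 2))}
        res1 = mctp_tukey(groups, seed=5)
        res2 = mctp_tukey({k: np.exp(v) for k, v in groups.items()}, seed=5)
        np.testing.assert_allclose(res1.estimates, res2.estimates)
        np.testing.assert_allclose(res1.p_adjusted, res2.p_adjusted, atol=1e-6)

    def test_seeded_reproducibility(self, rng):
        groups = {k: rng.normal(size=10) for k in "abc"}
        r1 = mctp_tukey(groups, seed=9)
        r2 = mctp_tukey(groups, seed=9)
        np.testing.assert_array_equal(r1.p_adjusted, r2.p_adjusted)
        np.testing.assert_array_equal(r1.ci_lower, r2.ci_lower)

    def test_small_group_warns(self):
        with pytest.warns(UserWarning, match="n=2"):
            mctp_tukey({"a": [1.0, 2.0], "b": [1.5, 2.5, 3.0, 4.0]})


class TestKruskalWallis:
    def test_identical_samples_zero_statistic(self):
        h, p = kruskal_wallis({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # ranks 1..6, group means 2 and 5: H = 12/(6*7) * 3*((2-3.5)^2+(5-3.5)^2)
        h, p = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert h == pytest.approx(12 / 42 * 3 * (1.5**2 + 1.5**2), abs=1e-9)
        assert h == pytest.approx(27 / 7)

    def test_rank_invariance_under_label_permutation(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=9)
        h1, _ = kruskal_wallis({"a": a, "b": b})
        h2, _ = kruskal_wallis({"b": b, "a": a})
        assert h1 == pytest.approx(h2)

    def test_all_identical_values(self):
        h, p = kruskal_wallis({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert h == 0.0 and p == 1.0


class TestMannWhitney:
    def test_separated_samples_u_zero(self):
        u, _ = mann_whitney([1, 2], [3, 4])
        assert u == 0.0  # convention: U counts pairs where a exceeds b

    def test_u_complementarity(self, rng):
        a, b = rng.normal(size=7), rng.normal(size=9)
        u1, _ = mann_whitney(a, b)
        u2, _ = mann_whitney(b, a)
        assert u1 + u2 == pytest.approx(7 * 9)

    def test_identical_samples_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = mann_whitney(x, x)
        assert p > 0.9

    def test_exact_enumeration_small_samples(self):
        # U=0 for {1,2} vs {3,4}: exact two-sided p = 2 * 1/C(4,2) = 1/3
        _, p = mann_whitney([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)


class TestChiSquare:
    def test_independent_table_zero_statistic(self):
        stat, df, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and df == 1 and p == pytest.approx(1.0)

    def test_direct_formula_oracle(self):
        table = np.array([[40, 15], [50, 112], [8, 7]], dtype=float)
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        oracle = ((table - expected) ** 2 / expected).sum()
        stat, df, _ = chi_square_independence(table)
        assert stat == pytest.approx(oracle, rel=1e-12)
        assert df == 2

    def test_transposition_invariance(self):
        t = [[12, 5, 9], [3, 14, 8]]
        s1, _, _ = chi_square_independence(t)
        s2, _, _ = chi_square_independence(np.transpose(t))
        assert s1 == pytest.approx(s2)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateInputError):
            chi_square_independence([[0, 0], [5, 3]])


class TestPercentageBend:
    def test_perfect_positive_correlation(self):
        x = np.arange(10.0)
        r, p = percentage_bend_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p == pytest.approx(0.0)

    def test_perfect_negative_correlation(self):
        x = np.arange(10.0)
        r, _ = percentage_bend_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_outlier_downweighted_vs_pearson(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        x[0], y[0] = 8.0, 9.0  # one gross outlier inducing spurious correlation
        pearson = np.corrcoef(x, y)[0, 1]
        r_pb, _ = percentage_bend_correlation(x, y)
        assert abs(r_pb) < abs(pearson)

    def test_matches_reference_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        from pingouin.correlation import percbend

        for beta in (0.1, 0.2, 0.3):
            x, y = rng.normal(size=30), rng.normal(size=30)
            r_ref, p_ref = percbend(x, y, beta=beta)
            r, p = percentage_bend_correlation(x, y, beta=beta)
            assert r == pytest.approx(r_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_constant_variable_undefined(self):
        with pytest.raises(DegenerateInputError):
            percentage_bend_correlation(np.ones(10), np.arange(10.0))
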