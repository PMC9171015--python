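"""Statistical layer: oracles, invariances, rate derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import cocscreen as cs
from cocscreen.errors import ParameterError


def chi_square_by_hand(counts: pd.DataFrame) -> float:
    """Independent oracle: direct sum of (O - E)^2 / E from the marginals."""
    obs = counts.to_numpy(dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


class TestContingencyChiSquare:
    def test_identical_rows_give_zero(self):
        counts = pd.DataFrame([[30, 10], [30, 10]], index=["a", "b"],
                              columns=["x", "y"])
        rep = cs.contingency_chi_square(counts)
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.p_value == pytest.approx(1.0)

    def test_matches_hand_computation(self, maturation_counts):
        rep = cs.contingency_chi_square(maturation_counts)
        assert rep.statistic == pytest.approx(
            chi_square_by_hand(maturation_counts), rel=1e-12
        )
        assert rep.df == 4

    def test_maximal_association_significant(self):
        counts = pd.DataFrame([[10, 0], [0, 10]], index=["a", "b"],
                              columns=["x", "y"])
        rep = cs.contingency_chi_square(counts)
        assert rep.p_value < 0.05

    def test_low_expected_cells_flagged(self):
        counts = pd.DataFrame([[2, 30], [3, 40]], index=["a", "b"],
                              columns=["x", "y"])
        rep = cs.contingency_chi_square(counts)
        assert rep.warnings

    def test_degenerate_table_rejected(self):
        with pytest.raises(ParameterError):
            cs.contingency_chi_square(pd.DataFrame([[1, 2]], index=["a"],
                                                   columns=["x", "y"]))

    def test_invariant_under_group_relabeling(self, maturation_counts):
        rep1 = cs.contingency_chi_square(maturation_counts)
        shuffled = maturation_counts.iloc[[3, 1, 4, 0, 2]]
        rep2 = cs.contingency_chi_square(shuffled)
        assert rep2.statistic == pytest.approx(rep1.statistic, rel=1e-12)


class TestPosthocZTests:
    def test_hand_formula_value(self):
        counts = pd.DataFrame([[30, 30], [15, 45]], index=["a", "b"],
                              columns=["x", "y"])
        [res] = cs.posthoc_proportion_ztests(counts, "x")
        p_pool = 45 / 120
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / 60 + 1 / 60))
        assert res.statistic == pytest.approx((0.5 - 0.25) / se, rel=1e-12)

    def test_identical_proportions_z_zero(self):
        counts = pd.DataFrame([[20, 20], [20, 20]], index=["a", "b"],
                              columns=["x", "y"])
        [res] = cs.posthoc_proportion_ztests(counts, "x")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.adjusted_p == 1.0

    def test_degenerate_pooled_proportion_falls_back_to_fisher(self):
        counts = pd.DataFrame([[0, 40], [0, 35]], index=["a", "b"],
                              columns=["x", "y"])
        [res] = cs.posthoc_proportion_ztests(counts, "x")
        assert res.method == "fisher"
        assert res.adjusted_p == 1.0

    def test_vs_reference_family_size(self, maturation_counts):
        res = cs.posthoc_proportion_ztests(
            maturation_counts, "MII", comparisons="vs-reference",
            reference="vehicle",
        )
        assert len(res) == 4
        # Bonferroni factor = 4 comparisons
        assert all(r.adjusted_p == pytest.approx(min(1.0, r.raw_p * 4)) for r in res)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_adjusted_p_bounds(self, seed):
        counts = cs.simulate_experiment_counts(
            {g: (0.7, 0.3) for g in "abcd"}, 50, seed=seed
        )
        for r in cs.posthoc_proportion_ztests(counts, counts.columns[0]):
            assert r.adjusted_p >= r.raw_p
            assert 0 <= r.adjusted_p <= 1


class TestAnovaTukey:
    def test_constant_groups_reported_as_no_effect(self):
        rep = cs.anova_tukey({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert rep.p_value == 1.0
        assert not any(p.significant for p in rep.pairwise)

    def test_two_group_tukey_equals_pooled_t(self):
        # closed form: studentized range with k=2 is sqrt(2)|t|
        g = {"a": [1.0, 2.0, 3.0, 2.5], "b": [4.0, 5.5, 6.0]}
        rep = cs.anova_tukey(g)
        t_p = sps.ttest_ind(g["a"], g["b"], equal_var=True).pvalue
        assert rep.pairwise[0].adjusted_p == pytest.approx(t_p, rel=1e-6)
        # and the ANOVA F equals t^2
        t_stat = sps.ttest_ind(g["a"], g["b"], equal_var=True).statistic
        assert rep.statistic == pytest.approx(t_stat**2, rel=1e-9)

    def test_needs_two_observations_per_group(self):
        with pytest.raises(ParameterError):
            cs.anova_tukey({"a": [1.0], "b": [2.0, 3.0]})


class TestKruskalDunn:
    def test_identical_groups(self):
        rep = cs.kruskal_dunn({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0

    def test_hand_computed_h(self):
        rep = cs.kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        # ranks 1..9, mean ranks 2/5/8: H = 12/(9*10) * 3*((2-5)^2+0+(8-5)^2)
        assert rep.statistic == pytest.approx(7.2, rel=1e-9)
        assert rep.df == 2

    def test_hand_computed_dunn_z(self):
        rep = cs.kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        # var_base = N(N+1)/12 = 7.5 (no ties); se = sqrt(7.5 * 2/3) = sqrt(5)
        z_ac = [p for p in rep.pairwise if {p.group_i, p.group_j} == {"a", "c"}][0]
        assert z_ac.statistic == pytest.approx((2 - 8) / np.sqrt(5), rel=1e-9)

    def test_tie_correction_matches_scipy(self):
        groups = {"a": [1, 1, 2, 3], "b": [2, 2, 3, 4], "c": [4, 4, 5, 5]}
        rep = cs.kruskal_dunn(groups)
        h, p = sps.kruskal(*groups.values())
        assert rep.statistic == pytest.approx(h, rel=1e-12)
        assert rep.p_value == pytest.approx(p, rel=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_h_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        groups = {g: rng.normal(i, 1, 6) for i, g in enumerate("abc")}
        rep1 = cs.kruskal_dunn(groups)
        rep2 = cs.kruskal_dunn({g: np.exp(v) for g, v in groups.items()})
        assert rep2.statistic == pytest.approx(rep1.statistic, rel=1e-9)


class TestDeriveRates:
    def test_worked_percentages(self, maturation_counts):
        rates = cs.derive_rates(maturation_counts, kind="meiotic")
        lookup = rates.set_index(["group", "category"])["percent_int"]
        assert lookup[("vehicle", "MII")] == 84
        assert lookup[("DES 1e-5 M", "MII")] == 3
        assert lookup[("control", "MII")] == 80

    def test_zero_count_category(self):
        counts = pd.DataFrame([[0, 50], [25, 25]], index=["a", "b"],
                              columns=["x", "y"])
        rates = cs.derive_rates(counts, kind="blastocyst")
        lookup = rates.set_index(["group", "category"])["percent_int"]
        assert lookup[("a", "x")] == 0

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_group_percentages_sum_to_100(self, seed):
        counts = cs.simulate_experiment_counts(
            {g: (0.2, 0.3, 0.5) for g in "abc"}, 77, seed=seed
        )
        rates = cs.derive_rates(counts, kind="cleavage")
        sums = rates.groupby("group")["percent"].sum()
        assert np.allclose(sums, 100.0)
        int_sums = rates.groupby("group")["percent_int"].sum()
        assert (abs(int_sums - 100) <= 2).all()  # rounding slack
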