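import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nucleofoci import (anova_tukey, bonferroni, linear_regression,
                        mann_whitney, mean_cells_per_field_from_totals,
                        pairwise_mann_whitney, summarize_group,
                        two_proportion_test)
from nucleofoci.image_io import InputError


def enumeration_p(x, y):
    """Independent oracle: two-sided permutation p for the U statistic,
    with U computed by direct pairwise comparison counting."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum((1.0 if a > b else 0.5 if a == b else 0.0)
                   for a in xs for b in ys)

    mu = n1 * len(y) / 2.0
    obs = abs(u_of(tuple(range(n1))) - mu)
    devs = [abs(u_of(idx) - mu)
            for idx in itertools.combinations(range(len(pooled)), n1)]
    return sum(d >= obs - 1e-12 for d in devs) / len(devs)


class TestMannWhitney:
    def test_single_pair(self):
        r = mann_whitney([1.0], [2.0], mode="exact")
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_separated_pairs(self):
        r = mann_whitney([1.0, 2.0], [3.0, 4.0], mode="exact")
        assert r.statistic == 0.0
        assert r.p_raw == pytest.approx(2.0 / 6.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 6))
        # integer values to provoke ties
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        r = mann_whitney(x, y, mode="exact")
        assert r.p_raw == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_auto_switches_to_normal_for_large_samples(self):
        rng = np.random.default_rng(1)
        r = mann_whitney(rng.random(20), rng.random(20) + 0.5)
        assert "normal" in r.test_name
        assert r.p_raw < 0.01

    def test_normal_mode_matches_tie_corrected_reference(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(1, 5, 25).astype(float)
        r = mann_whitney(x, y, mode="normal")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert r.p_raw == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney([], [1.0])


class TestBonferroni:
    @pytest.mark.parametrize("ps,expected", [
        ([0.03], [0.03]),
        ([0.01, 0.04], [0.02, 0.08]),
        ([0.6, 0.7], [1.0, 1.0]),
    ])
    def test_worked_examples(self, ps, expected):
        assert bonferroni(ps) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_monotone_and_capped(self, ps):
        adj = bonferroni(ps)
        assert all(0.0 <= a <= 1.0 for a in adj)
        assert all(a >= p for a, p in zip(adj, ps))
        order = np.argsort(ps)
        assert all(adj[order[i]] <= adj[order[i + 1]] + 1e-12
                   for i in range(len(ps) - 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bonferroni([0.5, 1.2])


class TestAnovaTukey:
    def test_identical_groups_null(self):
        res = anova_tukey([[1.0, 2, 3], [1.0, 2, 3]])
        omni = res[0]
        assert omni.statistic == 0.0 and omni.p_raw == 1.0

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        g1 = 0.0 + rng.normal(0, 1e-3, 3)
        g2 = 10.0 + rng.normal(0, 1e-3, 3)
        res = anova_tukey([g1, g2])
        assert res[0].p_raw < 1e-6

    def test_two_group_tukey_equals_studentized_range_transform(self):
        """With two groups, Tukey's p equals the pooled-variance two-sample
        comparison pushed through the studentized-range distribution."""
        rng = np.random.default_rng(3)
        g1 = rng.normal(0.0, 1.0, 8)
        g2 = rng.normal(1.0, 1.0, 8)
        res = anova_tukey([g1, g2])
        t = sps.ttest_ind(g1, g2, equal_var=True).statistic
        p_ref = sps.studentized_range.sf(abs(t) * math.sqrt(2.0), 2, 14)
        assert res[1].p_adjusted == pytest.approx(float(p_ref), rel=1e-4)

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            anova_tukey([[1.0], [1.0, 2.0]])


class TestRegression:
    def test_perfect_line(self):
        r = linear_regression([0, 1, 2], [0, 1, 2])
        assert (r.slope, r.intercept, r.r_squared) == (1.0, 0.0, 1.0)

    def test_hand_least_squares(self):
        r = linear_regression([0, 1, 2], [1, 1, 3])
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(2.0 / 3.0)

    def test_constant_x_rejected(self):
        with pytest.raises(InputError):
            linear_regression([2, 2, 2], [1, 2, 3])

    def test_negative_coupling_sign_recovered(self):
        rng = np.random.default_rng(5)
        k = rng.poisson(2.0, 300)
        y = 120.0 - 10.0 * k + rng.normal(0, 8.0, 300)
        r = linear_regression(k, y)
        assert r.slope < 0 and r.p_slope < 0.05


class TestTwoProportion:
    def test_equal_proportions_null(self):
        r = two_proportion_test(50, 100, 50, 100)
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_extreme_small_sample_uses_fisher(self):
        r = two_proportion_test(0, 10, 10, 10)
        assert r.test_name == "fisher-exact"
        # hypergeometric oracle: only the two extreme 2x2 tables are as rare
        p_obs = sps.hypergeom.pmf(0, 20, 10, 10)
        assert r.p_raw == pytest.approx(2 * p_obs, rel=1e-9)

    def test_z_matches_chi_square_oracle(self):
        k1, n1, k2, n2 = 30, 120, 55, 130
        r = two_proportion_test(k1, n1, k2, n2)
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        chi2 = sps.chi2_contingency(table, correction=False)
        assert r.p_raw == pytest.approx(float(chi2.pvalue), rel=1e-10)
        assert r.statistic**2 == pytest.approx(float(chi2.statistic), rel=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InputError):
            two_proportion_test(11, 10, 1, 10)


class TestGroupSummary:
    def _study(self, cells_per_field, counts):
        fields = pd.DataFrame({
            "field_id": [f"f{i}" for i in range(len(cells_per_field))],
            "subject_id": ["s1"] * len(cells_per_field),
            "cell_count": cells_per_field})
        nuclei = pd.DataFrame({
            "field_id": ["f0"] * len(counts),
            "focus_count": counts})
        return fields, nuclei

    def test_printed_group_totals_imply_printed_means(self):
        assert mean_cells_per_field_from_totals(4145, 10) == pytest.approx(
            51.81, abs=0.005)
        assert mean_cells_per_field_from_totals(1590, 5) == pytest.approx(
            39.75, abs=0.005)

    def test_totals_conserved_and_sems(self):
        fields, nuclei = self._study([10, 20, 30], [0, 1, 2, 3])
        s = summarize_group(fields, nuclei, "g")
        assert s.total_cells == 60
        assert s.mean_cells_per_field == pytest.approx(20.0)
        assert s.sem_cells_per_field == pytest.approx(10.0 / math.sqrt(3))
        assert s.mean_nuclear_inclusions_per_cell == pytest.approx(1.5)
        assert s.sem_nuclear_inclusions_per_cell == pytest.approx(
            np.std([0, 1, 2, 3], ddof=1) / 2.0)

    def test_zero_cell_field(self):
        fields = pd.DataFrame({"field_id": ["f0"], "subject_id": ["s1"],
                               "cell_count": [0]})
        s = summarize_group(fields, pd.DataFrame(columns=["focus_count"]), "g")
        assert s.total_cells == 0 and s.mean_cells_per_field == 0.0
        assert math.isnan(s.mean_nuclear_inclusions_per_cell)

    def test_no_fields_rejected(self):
        with pytest.raises(InputError):
            summarize_group(pd.DataFrame(columns=["field_id", "subject_id",
                                                  "cell_count"]),
                            pd.DataFrame(), "g")


def test_pairwise_family_size_is_all_pairs():
    rng = np.random.default_rng(11)
    samples = {f"g{i}": rng.normal(i, 1.0, 15) for i in range(4)}
    results = pairwise_mann_whitney(samples)
    assert len(results) == 6  # C(4,2) comparisons, the Bonferroni family
    for r in results:
        assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_raw))
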