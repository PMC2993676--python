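"""Differential expression: fold changes, tests, adjustment, selection,
clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gctmir.diffexp import (bh_adjust, differential_expression,
                            hierarchical_cluster, log2_fold_changes, select_de,
                            two_group_test)
from gctmir.io_core import ExpressionMatrix
from gctmir.synthetic_data import simulate_expression


def _matrix(data, groups):
    return ExpressionMatrix(pd.DataFrame(data), groups)


class TestFoldChanges:
    def test_identical_group_means_give_zero(self, small_matrix):
        fc = log2_fold_changes(small_matrix, "B")
        assert fc["flat"] == pytest.approx(0.0)
        assert fc["constant"] == pytest.approx(0.0)

    def test_simple_mean_difference(self, small_matrix):
        fc = log2_fold_changes(small_matrix, "B")
        assert fc["up_a"] == pytest.approx(4.0)
        assert fc["up_b"] == pytest.approx(-3.0)

    def test_matches_direct_mean_difference_oracle(self, rng):
        data = rng.normal(size=(30, 8))
        cols = [f"s{i}" for i in range(8)]
        m = _matrix(pd.DataFrame(data, columns=cols),
                    {c: ("A" if i < 5 else "B") for i, c in enumerate(cols)})
        fc = log2_fold_changes(m, "B")
        oracle = data[:, :5].mean(axis=1) - data[:, 5:].mean(axis=1)
        assert np.allclose(fc.to_numpy(), oracle, atol=1e-12)

    def test_feature_missing_in_whole_group_is_nan(self):
        df = pd.DataFrame([[np.nan, np.nan, 1.0, 2.0]],
                          index=["f"], columns=["a1", "a2", "b1", "b2"])
        m = ExpressionMatrix(df, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert np.isnan(log2_fold_changes(m, "B")["f"])


class TestTwoGroupTest:
    def test_pooled_t_matches_hand_computation(self):
        # {1,2,3} vs {4,5,6}: pooled sd 1, se = sqrt(2/3), |t| = 3/0.8165
        df = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["f"],
                          columns=list("abcdef"))
        m = ExpressionMatrix(df, dict(zip("abcdef", "AAABBB")))
        res = two_group_test(m, "B", method="student")
        assert abs(res["t"]["f"]) == pytest.approx(3.674, abs=5e-3)

    def test_label_swap_negates_t_keeps_p(self, rng):
        data = rng.normal(size=(20, 10))
        cols = [f"s{i}" for i in range(10)]
        ga = {c: ("A" if i < 5 else "B") for i, c in enumerate(cols)}
        m = _matrix(pd.DataFrame(data, columns=cols), ga)
        ra = two_group_test(m, "B")
        rb = two_group_test(m, "A")
        assert np.allclose(ra["t"], -rb["t"], atol=1e-12)
        assert np.allclose(ra["p"], rb["p"], atol=1e-12)

    def test_null_pvalues_uniform(self):
        m, _ = simulate_expression(8, 8, 5000, de_fraction=0.0, noise_sd=1.0,
                                   seed=13)
        res = two_group_test(m, "B", method="student")
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    @pytest.mark.parametrize("method", ["student", "welch"])
    def test_degenerate_zero_variance_conventions(self, method):
        df = pd.DataFrame([[1.0, 1, 1, 1, 1, 1], [1.0, 1, 1, 2, 2, 2]],
                          index=["same", "diff"], columns=list("abcdef"))
        m = ExpressionMatrix(df, dict(zip("abcdef", "AAABBB")))
        res = two_group_test(m, "B", method=method)
        assert res["p"]["same"] == 1.0
        assert res["p"]["diff"] == 0.0
        assert bool(res["degenerate"]["diff"])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_min_over_tail_formula(self):
        # step-up: p_(i) * n / i, monotone from the largest
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw_and_rank_preserving(self, rng):
        for _ in range(25):
            p = rng.uniform(size=40)
            adj = bh_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_alternative_methods_are_more_conservative(self, rng):
        p = rng.uniform(size=100)
        assert np.all(bh_adjust(p, method="by") >= bh_adjust(p) - 1e-12)


class TestSelectDe:
    def _table(self, fc, p_adj):
        return pd.DataFrame({"log2fc": fc, "p_adj": p_adj},
                            index=[f"f{i}" for i in range(len(fc))])

    def test_permissive_thresholds_select_all_split_by_sign(self):
        t = self._table([2.0, -3.0, 0.5], [1e-4, 1e-4, 1e-4])
        up_a, up_b = select_de(t, 0.0, 1.0)
        assert (set(up_a), set(up_b)) == ({"f0", "f2"}, {"f1"})

    def test_thresholds_are_strict_inequalities(self):
        t = self._table([1.5, 1.6], [0.005, 0.01])
        up_a, up_b = select_de(t, 1.5, 0.01)
        assert up_a == [] and up_b == []

    def test_symmetry_under_group_exchange(self, rng):
        m, _ = simulate_expression(6, 6, 300, de_fraction=0.2, effect_log2=2,
                                   noise_sd=0.5, seed=21)
        ta = differential_expression(m, "B")
        tb = differential_expression(m, "A")
        a_up, a_dn = select_de(ta, 1.0, 0.05)
        b_up, b_dn = select_de(tb, 1.0, 0.05)
        assert set(a_up) == set(b_dn) and set(a_dn) == set(b_up)

    def test_planted_recovery_sensitivity_and_direction(self):
        m, truth = simulate_expression(10, 10, 2000, de_fraction=0.05,
                                       effect_log2=3.0, noise_sd=0.5, seed=22)
        table = differential_expression(m, "B")
        up_a, up_b = select_de(table, 1.0, 0.01)
        sel = set(up_a) | set(up_b)
        de = set(truth.de_features)
        assert len(sel & de) / len(de) > 0.95
        for f in up_a:
            if f in truth.de_features:
                assert truth.de_features[f] > 0

    def test_null_fdr_controlled(self):
        m, _ = simulate_expression(8, 8, 2000, de_fraction=0.0, noise_sd=1.0,
                                   seed=23)
        table = differential_expression(m, "B")
        frac = (table["p_adj"] < 0.1).mean()
        assert frac <= 0.1


class TestClustering:
    def test_well_separated_groups_have_pure_clusters(self):
        m, truth = simulate_expression(6, 6, 100, de_fraction=0.3,
                                       effect_log2=4.0, noise_sd=0.3, seed=31)
        table = differential_expression(m, "B")
        feats = list(table.index[table["p_adj"] < 1e-3])
        res = hierarchical_cluster(m, feats)
        assert res.purity == 1.0
        assert sorted(res.sample_order) == sorted(m.sample_ids)

    def test_one_sample_per_group_is_trivially_pure(self):
        df = pd.DataFrame([[0.0, 5.0], [0.0, 5.0]], index=["f1", "f2"],
                          columns=["s1", "s2"])
        m = ExpressionMatrix(df, {"s1": "A", "s2": "B"})
        res = hierarchical_cluster(m, ["f1", "f2"])
        assert res.purity == 1.0
        assert res.newick.endswith(";")

    def test_duplicated_sample_clusters_adjacent_to_its_twin(self, rng):
        data = rng.normal(size=(50, 6))
        data[:, 3] = data[:, 0]  # s3 duplicates s0
        cols = [f"s{i}" for i in range(6)]
        m = _matrix(pd.DataFrame(data, columns=cols),
                    {c: ("A" if i < 3 else "B") for i, c in enumerate(cols)})
        res = hierarchical_cluster(m, list(m.feature_ids))
        i, j = res.sample_order.index("s0"), res.sample_order.index("s3")
        assert abs(i - j) == 1

    def test_constant_features_do_not_break_distance(self, small_matrix):
        res = hierarchical_cluster(small_matrix, ["constant"])
        assert len(res.sample_order) == 6

    def test_empty_feature_subset_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            hierarchical_cluster(small_matrix, [])
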