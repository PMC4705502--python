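"""ANP priorities, consistency, supermatrix, limit and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import danp_select as ds
from danp_select.anp_core import RANDOM_INDEX, round_half_up
from danp_select.network_model import ALTERNATIVES

from conftest import random_reciprocal


def cmatrix(values, labels=None, context="ctx"):
    values = np.asarray(values, float)
    labels = labels or [f"e{i}" for i in range(values.shape[0])]
    return ds.ComparisonMatrix(labels, values, context)


class TestValidateReciprocal:
    def test_cost_example_is_valid(self, case_study):
        _, frags = case_study
        assert ds.validate_reciprocal(frags["comparison_example"]).valid

    def test_broken_reciprocity_reported(self):
        rep = ds.validate_reciprocal(cmatrix([[1, 2], [0.6, 1]]))
        assert rep.reciprocity_violations == [(0, 1)]
        assert not rep.valid

    def test_equal_importance_matrix_is_valid(self):
        assert ds.validate_reciprocal(cmatrix(np.ones((3, 3)))).valid

    def test_non_positive_entry_raises(self):
        with pytest.raises(ds.ValidationError, match="non-positive"):
            ds.validate_reciprocal(cmatrix([[1, 0], [9, 1]]))

    def test_out_of_scale_reported(self):
        rep = ds.validate_reciprocal(cmatrix([[1, 12], [1 / 12, 1]]))
        assert rep.range_violations


class TestPriorities:
    def test_cost_example_weights_and_eigenvalue(self, case_study):
        _, frags = case_study
        pr = ds.principal_priorities(frags["comparison_example"])
        np.testing.assert_allclose(pr.weights, [0.7660, 0.0426, 0.1915], atol=5e-4)
        assert pr.lambda_max == pytest.approx(3.5, abs=1e-9)

    def test_consistent_matrix_recovery(self):
        w = np.array([0.5, 0.3, 0.2])
        pr = ds.principal_priorities(cmatrix(np.outer(w, 1 / w)))
        np.testing.assert_allclose(pr.weights, w, atol=1e-12)
        assert pr.lambda_max == pytest.approx(3.0, abs=1e-10)

    def test_all_ones_uniform(self):
        pr = ds.principal_priorities(cmatrix(np.ones((5, 5))))
        np.testing.assert_allclose(pr.weights, 0.2, atol=1e-12)
        assert pr.lambda_max == pytest.approx(5.0, abs=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_three_by_three_row_geometric_mean_closed_form(self, seed):
        """For every 3x3 reciprocal matrix the principal eigenvector equals
        the normalized row geometric means (independent closed form)."""
        A = random_reciprocal(3, np.random.default_rng(seed))
        pr = ds.principal_priorities(cmatrix(A))
        gm = A.prod(axis=1) ** (1 / 3)
        np.testing.assert_allclose(pr.weights, gm / gm.sum(), atol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 7))
    def test_lambda_max_at_least_n(self, seed, n):
        A = random_reciprocal(n, np.random.default_rng(seed))
        pr = ds.principal_priorities(cmatrix(A))
        assert pr.lambda_max >= n - 1e-9

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 8))
    def test_consistent_recovery_and_zero_cr(self, seed, n):
        """Priorities built from a_ij = w_i/w_j recover w and give CR = 0."""
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.05, 1.0, size=n)
        w = w / w.sum()
        pr = ds.principal_priorities(cmatrix(np.outer(w, 1 / w)))
        np.testing.assert_allclose(pr.weights, w, atol=1e-10)
        if n <= 10:
            assert ds.consistency(pr.lambda_max, n).CR == pytest.approx(0.0, abs=1e-8)


class TestConsistency:
    def test_cost_example_unacceptable(self):
        rep = ds.consistency(3.5, 3)
        assert rep.CI == pytest.approx(0.25)
        assert rep.CR == pytest.approx(0.25 / 0.58, abs=1e-9)
        assert not rep.acceptable

    def test_fully_consistent(self):
        rep = ds.consistency(4.0, 4)
        assert rep.CI == 0.0 and rep.CR == 0.0 and rep.acceptable

    def test_order_two_always_consistent(self):
        assert ds.consistency(2.0, 2).CR == 0.0

    def test_order_above_table_rejected(self):
        with pytest.raises(ds.ValidationError, match="random index"):
            ds.consistency(12.0, 11)

    def test_inconsistent_order_two_flags_upstream_bug(self):
        with pytest.raises(ds.ValidationError):
            ds.consistency(2.5, 2)

    def test_random_index_table(self):
        assert RANDOM_INDEX == {2: 0.0, 3: 0.58, 4: 0.9, 5: 1.12, 6: 1.24,
                                7: 1.32, 8: 1.41, 9: 1.45, 10: 1.51}


class TestSupermatrix:
    def test_case_study_shape_and_blocks(self, clean_bundle):
        result, group = clean_bundle
        run = ds.run_anp(result.network, group)
        sm = run.supermatrix
        assert sm.raw.shape == (24, 24)
        alt_sl = sm.cluster_slices[ALTERNATIVES]
        np.testing.assert_allclose(sm.raw[alt_sl, alt_sl], np.eye(6))
        # every sub-criterion column carries an alternatives block
        for e in result.network.subcriteria():
            col = sm.node_order.index(e)
            assert sm.raw[alt_sl, col].sum() > 0

    def test_no_declared_blocks_flagged_non_rankable(self):
        net = ds.DecisionNetwork(
            "g",
            [ds.Cluster("C", "criterion", ["x", "y"])],
            ["a", "b"],
            blocks=[],
        )
        sm = ds.build_supermatrix(net, {}, None)
        assert sm.raw[:2, :2].sum() == 0  # nothing feeds the criteria columns
        from danp_select.anp_core import default_cluster_weight_matrix

        with pytest.raises(ds.DegenerateInputError, match="incoming"):
            ds.weight_supermatrix(sm, default_cluster_weight_matrix(net, sm), net)

    def test_missing_priorities_named(self):
        net = ds.DecisionNetwork(
            "g",
            [ds.Cluster("C", "criterion", ["x", "y"])],
            ["a", "b"],
            blocks=[ds.Block(ALTERNATIVES, "C")],
        )
        with pytest.raises(ds.PipelineError, match="'x'"):
            ds.build_supermatrix(net, {"y": np.array([0.5, 0.5])}, None)

    def test_hierarchy_is_block_triangular(self):
        net = ds.DecisionNetwork(
            "g",
            [ds.Cluster("C", "criterion", ["x", "y"])],
            ["a", "b"],
            blocks=[ds.Block(ALTERNATIVES, "C")],
        )
        sm = ds.build_supermatrix(
            net, {"x": np.array([0.7, 0.3]), "y": np.array([0.2, 0.8])}, None
        )
        assert sm.raw[:2, :].sum() == 0  # criteria rows receive nothing

    def test_weighted_columns_sum_to_one(self, synth_bundle):
        result, group = synth_bundle
        for run in (ds.run_anp(result.network, group),
                    ds.run_danp(result.network, group)):
            np.testing.assert_allclose(run.supermatrix.weighted.sum(axis=0), 1.0,
                                       atol=1e-9)
            np.testing.assert_allclose(run.supermatrix.limit.sum(axis=0), 1.0,
                                       atol=1e-8)


class TestLimit:
    def test_identical_columns_fixed_point(self):
        col = np.array([0.2, 0.3, 0.5])
        W = np.tile(col[:, None], (1, 3))
        limit, method = ds.limit_supermatrix(W)
        np.testing.assert_allclose(limit, W, atol=1e-12)
        assert method == "power"

    def test_period_two_cesaro_average(self):
        limit, method = ds.limit_supermatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(limit, np.full((2, 2), 0.5))
        assert method == "cesaro"

    def test_hierarchy_limit_composes_priorities(self):
        # 2 criteria (weights .6/.4 folded into the weighted matrix) feeding
        # 2 absorbing alternatives: the limit column of each criterion must be
        # its alternative priorities, composed exactly as a weighted sum.
        p1, p2 = np.array([0.7, 0.3]), np.array([0.2, 0.8])
        W = np.zeros((4, 4))
        W[2:, 0] = p1
        W[2:, 1] = p2
        W[2:, 2:] = np.eye(2)
        limit, _ = ds.limit_supermatrix(W)
        np.testing.assert_allclose(limit[2:, 0], p1, atol=1e-10)
        np.testing.assert_allclose(limit[2:, 1], p2, atol=1e-10)

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(6, 10))
    def test_matches_repeated_multiplication_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.01, 1.0, size=(n, n))
        W = W / W.sum(axis=0)
        limit, _ = ds.limit_supermatrix(W)
        P = np.eye(n)
        for _ in range(3000):
            P = W @ P
        np.testing.assert_allclose(limit, P, atol=1e-8)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ds.DegenerateInputError):
            ds.limit_supermatrix(np.array([[0.5, 0.2], [0.2, 0.5]]))


class TestBlockNormalizeAndWeights:
    def test_unit_mode_cluster_sums(self, synth_bundle):
        result, group = synth_bundle
        wt = ds.run_danp(result.network, group).weight_table
        sums = wt.elements.groupby("cluster")["LW"].sum()
        np.testing.assert_allclose(sums.values, 1.0, atol=1e-9)
        assert wt.alternatives["score"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_paper_mode_halves_criterion_blocks(self, synth_bundle):
        result, group = synth_bundle
        unit = ds.run_danp(result.network, group, block_norm="unit").weight_table
        paper = ds.run_danp(result.network, group, block_norm="paper").weight_table
        crit = unit.elements["cluster"] != "Strategies"
        np.testing.assert_allclose(
            paper.elements.loc[crit, "LW"].values,
            0.5 * unit.elements.loc[crit, "LW"].values,
            atol=1e-12,
        )
        np.testing.assert_allclose(
            paper.alternatives["score"].values,
            0.5 * unit.alternatives["score"].values,
            atol=1e-12,
        )
        assert paper.alternatives["score"].sum() == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize(
        "lw,rw,expected",
        [(0.21883, 0.25, 0.05471), (0.09655, 0.25, 0.02414), (0.0, 0.0, 0.0)],
    )
    def test_global_weight_product(self, lw, rw, expected):
        assert round_half_up(float(ds.global_weights(lw, rw)), 5) == expected


class TestRanking:
    def test_case_study_alternative_order(self):
        from danp_select.synth_fixtures import CASE_STUDY_ALTERNATIVE_WEIGHTS

        ranking = ds.rank_alternatives(CASE_STUDY_ALTERNATIVE_WEIGHTS)
        assert ranking.order == ["C4", "C3", "C2", "C5", "C6", "C1"]

    def test_full_tie_keeps_label_order(self):
        ranking = ds.rank_alternatives({"b": 1.0, "a": 1.0, "c": 1.0})
        assert ranking.order == ["b", "a", "c"]
        assert ranking.full_tie

    def test_single_alternative(self):
        ranking = ds.rank_alternatives({"only": 0.3})
        assert ranking.order == ["only"] and not ranking.full_tie
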