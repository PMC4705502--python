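"""Change scenarios, rank stability and judgment-count accounting."""

import numpy as np
import pytest

import danp_select as ds


@pytest.fixture(scope="module")
def scenario_base(synth_bundle):
    result, group = synth_bundle
    return result.network, group


class TestDuplicateAlternative:
    def test_clone_structure(self, scenario_base):
        net, js = scenario_base
        sc = ds.add_duplicate_alternative(net, js, "A4")
        assert sc.network.alternatives == net.alternatives + ["A4_clone"]
        for e in net.subcriteria():
            m = sc.judgments.anp_matrices[e]
            assert m.n == 7
            tgt = m.labels.index("A4")
            # clone row/column copy the target's comparisons, mutual = 1
            others = [i for i in range(6) if i != tgt]
            np.testing.assert_allclose(m.values[6, others], m.values[tgt, others])
            np.testing.assert_allclose(m.values[others, 6], m.values[others, tgt])
            assert m.values[6, tgt] == 1.0 and m.values[tgt, 6] == 1.0

    def test_reciprocity_preserved(self, scenario_base):
        net, js = scenario_base
        sc = ds.add_duplicate_alternative(net, js, "A1")
        for e in net.subcriteria():
            A = sc.judgments.anp_matrices[e].values
            np.testing.assert_allclose(A * A.T, 1.0, atol=1e-9)

    def test_clone_into_single_alternative_model_splits_mass(self):
        net = ds.DecisionNetwork(
            "g",
            [ds.Cluster("C", "criterion", ["crit"])],
            ["only"],
            blocks=[ds.Block(ds.ALTERNATIVES, "C")],
        )
        js = ds.JudgmentSet("p")
        sc = ds.add_duplicate_alternative(net, js, "only")
        run = ds.run_anp(sc.network, sc.judgments)
        assert run.ranking.scores["only"] == pytest.approx(0.5)
        assert run.ranking.scores["only_clone"] == pytest.approx(0.5)

    def test_unknown_target(self, scenario_base):
        net, js = scenario_base
        with pytest.raises(ds.SchemaError):
            ds.add_duplicate_alternative(net, js, "nope")


class TestDuplicateSubcriterion:
    def test_cluster_grows_and_judgments_copied(self, scenario_base):
        net, js = scenario_base
        cluster = net.criterion_clusters()[2].label  # size 3
        target = net.cluster(cluster).elements[0]
        sc = ds.add_duplicate_subcriterion(net, js, cluster, target)
        assert len(sc.network.cluster(cluster).elements) == 4
        assert sc.judgments.anp_matrices[cluster].n == 4
        assert sc.judgments.dematel_matrices[cluster].n == 4
        # the clone's alternatives matrix copies the target's
        np.testing.assert_allclose(
            sc.judgments.anp_matrices[f"{target}_clone"].values,
            js.anp_matrices[target].values,
        )

    def test_influence_diagonal_stays_zero(self, scenario_base):
        net, js = scenario_base
        cluster = net.criterion_clusters()[0].label
        target = net.cluster(cluster).elements[1]
        sc = ds.add_duplicate_subcriterion(net, js, cluster, target)
        assert np.all(np.diag(sc.judgments.dematel_matrices[cluster].values) == 0)

    def test_scenario_is_runnable(self, scenario_base):
        net, js = scenario_base
        cluster = net.criterion_clusters()[3].label
        target = net.cluster(cluster).elements[-1]
        sc = ds.add_duplicate_subcriterion(net, js, cluster, target)
        run = ds.run_danp(sc.network, sc.judgments)
        assert f"{target}_clone" in run.weight_table.elements["element"].values

    def test_unknown_cluster_or_target(self, scenario_base):
        net, js = scenario_base
        with pytest.raises(ds.SchemaError):
            ds.add_duplicate_subcriterion(net, js, "nope", "S1")
        with pytest.raises(ds.SchemaError):
            ds.add_duplicate_subcriterion(net, js, net.clusters[1].label, "nope")


class TestRankStability:
    def test_identical_orders(self):
        rep = ds.rank_stability(list("abc"), list("abc"))
        assert rep.preserved and rep.kendall_tau == pytest.approx(1.0)
        assert all(v == 0 for v in rep.displacements.values())

    def test_best_falls_to_penultimate(self):
        """The classic rank-reversal failure: the former best alternative
        drops to fifth of six once its clone enters."""
        before = ["C4", "C3", "C2", "C5", "C6", "C1"]
        after = ["C3", "C2", "C5", "C6", "C4", "C4_clone", "C1"]
        rep = ds.rank_stability(before, after)
        assert not rep.preserved
        assert rep.displacements["C4"] == 4
        assert rep.kendall_tau < 1.0

    def test_full_reversal(self):
        rep = ds.rank_stability(list("abcdef"), list("fedcba"))
        assert rep.kendall_tau == pytest.approx(-1.0)

    def test_missing_item_rejected(self):
        with pytest.raises(ds.DanpError):
            ds.rank_stability(["a", "b"], ["a"])


class TestJudgmentCounts:
    def test_case_study_totals(self, case_study):
        net, _ = case_study
        assert ds.count_judgments(net, "anp") == 500
        assert ds.count_judgments(net, "danp") == 550

    def test_degenerate_model_counts_zero(self):
        net = ds.DecisionNetwork(
            "g", [ds.Cluster("C", "criterion", ["e"])], ["a"]
        )
        assert ds.count_judgments(net, "anp") == 0
        assert ds.count_judgments(net, "danp") == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        """Count must equal walking the actually generated elicitation forms
        and counting their off-diagonal cells."""
        rng = np.random.default_rng(seed)
        spec = ds.SynthesisSpec(
            n_strategies=int(rng.integers(1, 4)),
            cluster_sizes=tuple(int(x) for x in rng.integers(1, 5, size=rng.integers(1, 4))),
            n_alternatives=int(rng.integers(2, 6)),
            n_participants=1,
            seed=seed,
        )
        result = ds.synthesize(spec)
        js = result.judgment_sets[0]
        anp_cells = sum(m.n * (m.n - 1) for m in js.anp_matrices.values())
        dem_cells = sum(m.n * (m.n - 1) for m in js.dematel_matrices.values())
        assert ds.count_judgments(result.network, "anp") == anp_cells
        assert ds.count_judgments(result.network, "danp") == anp_cells + dem_cells


class TestIncrementalJudgments:
    def test_extra_alternative_costs_twelve_per_subcriterion(self, case_study):
        net, _ = case_study
        delta = ds.incremental_judgments(
            net, {"kind": "add_alternative", "clone_of": "C4"}, "anp"
        )
        assert delta.detail["per_alternative_matrix"] == 12
        assert delta.detail["alternative_matrices"] == 15
        assert delta.total == 180
        # the same increment applies to both methods
        danp = ds.incremental_judgments(
            net, {"kind": "add_alternative", "clone_of": "C4"}, "danp"
        )
        assert danp.total == delta.total

    @pytest.mark.parametrize("method,expected", [("anp", 30), ("danp", 36)])
    def test_extra_subcriterion_in_cost_cluster(self, case_study, method, expected):
        net, _ = case_study
        delta = ds.incremental_judgments(
            net, {"kind": "add_subcriterion", "cluster": "Cost"}, method
        )
        assert delta.total == expected

    def test_alternative_increment_equals_total_difference(self, case_study, synth_bundle):
        net, _ = case_study
        result, js = synth_bundle
        sc = ds.add_duplicate_alternative(result.network, js, "A1")
        for method in ("anp", "danp"):
            delta = ds.incremental_judgments(
                result.network, sc.change, method
            )
            assert delta.total == (
                ds.count_judgments(sc.network, method)
                - ds.count_judgments(result.network, method)
            )

    def test_subcriterion_increment_known_deviation(self, synth_bundle):
        """The published accounting excludes the enlarged within-cluster
        comparison matrix (2c ordered cells); the internally consistent
        count equals the before/after difference for both methods."""
        result, js = synth_bundle
        net = result.network
        cluster = net.criterion_clusters()[1].label
        c = len(net.cluster(cluster).elements)
        target = net.cluster(cluster).elements[0]
        sc = ds.add_duplicate_subcriterion(net, js, cluster, target)
        for method in ("anp", "danp"):
            published = ds.incremental_judgments(net, sc.change, method)
            full = ds.incremental_judgments(
                net, sc.change, method, include_within_cluster=True
            )
            diff = ds.count_judgments(sc.network, method) - ds.count_judgments(
                net, method
            )
            assert full.total == diff
            assert diff - published.total == 2 * c
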