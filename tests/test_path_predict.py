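import itertools

import numpy as np
import pytest

from perturbnet.graph_core import Network
from perturbnet.path_predict import (
    GoRuleSet,
    PathCandidate,
    enumerate_paths,
    filter_and_merge,
    mine_go_rules,
    path_coexpression,
    rule_score,
    score_paths,
)
from conftest import build_network, simple_expression


class TestMineGoRules:
    def test_single_edge(self):
        rules = mine_go_rules([("U", "V")], {"U": frozenset({"T1"}), "V": frozenset({"T2"})})
        assert rules.rules[("T1", "T2")] == (1, 1.0)
        assert rules.rules[("T2", "T1")] == (1, 1.0)

    def test_no_edges_gives_empty_set(self):
        rules = mine_go_rules([], {"U": frozenset({"T1"})})
        assert len(rules) == 0

    def test_shared_term_pair_accumulates_support(self):
        ann = {
            "A": frozenset({"T1"}),
            "B": frozenset({"T2"}),
            "C": frozenset({"T1"}),
            "D": frozenset({"T2"}),
        }
        rules = mine_go_rules([("A", "B"), ("C", "D")], ann)
        support, conf = rules.rules[("T1", "T2")]
        assert support == 2
        assert conf == pytest.approx(1.0)  # 2 supports / 2 proteins with T1

    def test_confidence_normalizes_by_antecedent_count(self):
        # three proteins annotated T1, only one participates in a T1->T2 edge
        ann = {
            "A": frozenset({"T1"}),
            "B": frozenset({"T2"}),
            "C": frozenset({"T1"}),
            "D": frozenset({"T1"}),
        }
        rules = mine_go_rules([("A", "B"), ("C", "D")], ann)
        assert rules.rules[("T1", "T2")][1] == pytest.approx(1 / 3)

    def test_empty_annotations_warn(self):
        with pytest.warns(UserWarning, match="empty annotation"):
            rules = mine_go_rules([("A", "B")], {})
        assert len(rules) == 0


def brute_force_paths(net, source, sink, max_nodes):
    """Independent recursive DFS enumeration of simple paths."""
    found = []

    def walk(path):
        if path[-1] == sink:
            found.append(tuple(path))
            return
        if len(path) == max_nodes:
            return
        for nxt in sorted(net.neighbors(path[-1])):
            if nxt not in path:
                walk(path + [nxt])

    walk([source])
    return sorted(found)


class TestEnumeratePaths:
    def test_chain(self):
        net = build_network([("A", "B"), ("B", "C")])
        paths = enumerate_paths(net, "A", "C")
        assert [p.nodes for p in paths] == [("A", "B", "C")]

    def test_k4_bounded_length(self):
        net = build_network(itertools.combinations("ABCD", 2))
        paths = enumerate_paths(net, "A", "D", max_nodes=3)
        assert {p.nodes for p in paths} == {("A", "D"), ("A", "B", "D"), ("A", "C", "D")}

    def test_no_direct_edge_with_two_node_budget(self):
        net = build_network([("A", "B"), ("B", "C")])
        assert enumerate_paths(net, "A", "C", max_nodes=2) == []

    def test_disconnected_pair_gives_empty_list(self):
        net = build_network([("A", "B")], nodes=["Z"])
        assert enumerate_paths(net, "A", "Z") == []

    def test_lexicographic_order(self):
        net = build_network(itertools.combinations("ABCD", 2))
        paths = enumerate_paths(net, "A", "D", max_nodes=4)
        seqs = [p.nodes for p in paths]
        assert seqs == sorted(seqs)

    def test_matches_dfs_oracle_on_random_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            nodes = [f"N{i}" for i in range(n)]
            net = build_network([], nodes=nodes)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        net.add_edge(nodes[i], nodes[j])
            max_nodes = int(rng.integers(2, 7))
            got = [p.nodes for p in enumerate_paths(net, "N0", "N1", max_nodes)]
            assert got == brute_force_paths(net, "N0", "N1", max_nodes)


class TestPathScoring:
    def test_identical_profiles_give_unit_coexpression(self):
        expr = simple_expression({"A": [1.0, 3.0, 2.0], "B": [1.0, 3.0, 2.0]})
        p = PathCandidate(nodes=("A", "B"))
        assert path_coexpression(p, expr) == pytest.approx(1.0)

    def test_mean_over_consecutive_pairs(self, rng):
        profiles = {g: list(rng.normal(size=20)) for g in "ABC"}
        expr = simple_expression(profiles)
        p = PathCandidate(nodes=("A", "B", "C"))
        got = path_coexpression(p, expr)
        expected = np.mean(
            [
                np.corrcoef(profiles["A"], profiles["B"])[0, 1],
                np.corrcoef(profiles["B"], profiles["C"])[0, 1],
            ]
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_gene_flags_unscorable(self):
        expr = simple_expression({"A": [1.0, 2.0, 3.0]})
        p = PathCandidate(nodes=("A", "MISSING"))
        assert np.isnan(path_coexpression(p, expr))
        assert not p.scorable

    def test_random_profiles_center_near_zero(self, rng):
        vals = []
        for _ in range(100):
            profiles = {g: list(rng.normal(size=30)) for g in "ABCD"}
            expr = simple_expression(profiles)
            p = PathCandidate(nodes=("A", "B", "C", "D"))
            vals.append(path_coexpression(p, expr))
        assert abs(np.mean(vals)) < 0.05
        assert np.mean(np.abs(np.array(vals)) < 0.2) >= 0.85

    def test_score_paths_matches_per_path_scoring(self, rng):
        profiles = {g: list(rng.normal(size=15)) for g in "ABCDE"}
        expr = simple_expression(profiles)
        paths = [PathCandidate(nodes=("A", "B", "C")), PathCandidate(nodes=("C", "D", "E"))]
        score_paths(paths, expr)
        for p in paths:
            single = PathCandidate(nodes=p.nodes)
            assert p.avg_coexpression == pytest.approx(
                path_coexpression(single, expr), abs=1e-9
            )


class TestRuleScore:
    def test_unannotated_path_scores_zero(self):
        p = PathCandidate(nodes=("A", "B", "C"))
        assert rule_score(p, GoRuleSet(), {}) == 0.0

    def test_full_confidence_path(self):
        rules = GoRuleSet({("T1", "T2"): (1, 1.0), ("T2", "T3"): (1, 1.0)})
        ann = {"A": frozenset({"T1"}), "B": frozenset({"T2"}), "C": frozenset({"T3"})}
        p = PathCandidate(nodes=("A", "B", "C"))
        assert rule_score(p, rules, ann) == pytest.approx(1.0)

    def test_mixed_confidences_average(self):
        rules = GoRuleSet({("T1", "T2"): (1, 0.5), ("T2", "T3"): (1, 1.0)})
        ann = {"A": frozenset({"T1"}), "B": frozenset({"T2"}), "C": frozenset({"T3"})}
        p = PathCandidate(nodes=("A", "B", "C"))
        assert rule_score(p, rules, ann) == pytest.approx(0.75)

    def test_best_matching_rule_is_used_per_pair(self):
        rules = GoRuleSet({("T1", "T2"): (1, 0.3), ("T1b", "T2"): (1, 0.9)})
        ann = {"A": frozenset({"T1", "T1b"}), "B": frozenset({"T2"})}
        p = PathCandidate(nodes=("A", "B"))
        assert rule_score(p, rules, ann) == pytest.approx(0.9)


class TestFilterAndMerge:
    def _scored_paths(self, rng):
        net = build_network(itertools.combinations("ABCD", 2))
        profiles = {g: list(rng.normal(size=25)) for g in "ABCD"}
        expr = simple_expression(profiles)
        paths = enumerate_paths(net, "A", "D", max_nodes=4)
        score_paths(paths, expr)
        return net, paths

    def test_permissive_thresholds_keep_everything(self, rng):
        net, paths = self._scored_paths(rng)
        merged, kept = filter_and_merge(
            paths, net, coexpr_threshold=-1.0, alpha=1.0, rng=0
        )
        assert len(kept) == len(paths)
        all_edges = {e for p in paths for e in p.edges}
        assert merged.edges() == all_edges

    def test_impossible_coexpression_threshold_empties_network(self, rng):
        net, paths = self._scored_paths(rng)
        with pytest.warns(UserWarning, match="no paths survive"):
            merged, kept = filter_and_merge(
                paths, net, coexpr_threshold=1.01, alpha=1.0, rng=0
            )
        assert kept == [] and merged.number_of_edges() == 0

    def test_monotone_shrinkage_in_coexpression_threshold(self, rng):
        net, paths = self._scored_paths(rng)
        edge_sets = []
        for thr in (-1.0, 0.0, 0.5):
            merged, _ = filter_and_merge(
                paths, net, coexpr_threshold=thr, alpha=1.0, rng=0
            )
            edge_sets.append(merged.edges())
        assert edge_sets[2] <= edge_sets[1] <= edge_sets[0]

    def test_output_is_subgraph_on_surviving_paths(self, rng):
        net, paths = self._scored_paths(rng)
        merged, kept = filter_and_merge(
            paths, net, coexpr_threshold=0.0, alpha=1.0, rng=0
        )
        assert merged.edges() <= net.edges()
        covered = {e for p in kept for e in p.edges}
        assert merged.edges() == covered
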