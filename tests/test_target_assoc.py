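import numpy as np
import pytest
from scipy import stats

from perturbnet.expr_stats import PerturbationDesign
from perturbnet.graph_core import GeneSet, adjacency
from perturbnet.synthetic import ScenarioSpec, make_expression
from perturbnet.target_assoc import (
    connectivity,
    connectivity_p,
    de_nodes,
    kuiper_p,
    leading_edges,
    two_hop,
    two_hop_reachable,
    weighted_kuiper,
)
from conftest import build_expression, build_network, simple_expression


def random_adjacency(rng, n, p=0.15):
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


class TestTwoHop:
    def test_chain_has_two_hop_path(self):
        net = build_network([("I", "J"), ("J", "K")])
        a = adjacency(net, ["I", "J", "K"])
        assert two_hop(a, 0, 2) == 1

    def test_direct_edge_without_shared_neighbor_is_zero(self):
        net = build_network([("I", "K")])
        a = adjacency(net, ["I", "K"])
        assert two_hop(a, 0, 1) == 0

    def test_same_node_is_error(self):
        a = np.zeros((3, 3), dtype=np.int8)
        with pytest.raises(ValueError):
            two_hop(a, 1, 1)

    def test_agrees_with_matrix_square_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 50))
            a = random_adjacency(rng, n)
            sq = (a.astype(int) @ a.astype(int)) > 0
            for i in range(n):
                reach = two_hop_reachable(a, i)
                expected = sq[i].copy()
                expected[i] = False
                assert (reach == expected).all()
            # spot-check the scalar form
            i, k = rng.choice(n, size=2, replace=False)
            assert two_hop(a, int(i), int(k)) == int(sq[i, k])


class TestConnectivity:
    def test_star_leaves_reach_each_other_via_hub(self, star):
        ordering = star.node_list()
        a = adjacency(star, ordering)
        idx = {n: i for i, n in enumerate(ordering)}
        leaves = [n for n in ordering if n != "HUB"]
        c = connectivity(a, idx[leaves[0]], [idx[x] for x in leaves[1:]])
        assert c == len(leaves) - 1

    def test_edgeless_graph_gives_zero(self):
        a = np.zeros((4, 4), dtype=np.int8)
        assert connectivity(a, 0, [1, 2, 3]) == 0

    def test_only_direct_neighbors_do_not_count(self):
        net = build_network([("I", "A"), ("I", "B")])
        a = adjacency(net, ["A", "B", "I"])
        # A and B are adjacent to I and 2-hop reachable from each other via I,
        # but from I itself the only 2-hop targets are... A and B (via each
        # other? no: A-I-B means A and B are mutual 2-hop; I's 2-hop set is empty)
        assert connectivity(a, 2, [0, 1]) == 0

    def test_monotone_under_edge_and_target_addition(self, rng):
        a = random_adjacency(rng, 20)
        targets = list(rng.choice(np.arange(1, 20), size=5, replace=False))
        c0 = connectivity(a, 0, targets)
        extra = [t for t in range(1, 20) if t not in targets][0]
        assert connectivity(a, 0, targets + [extra]) >= c0
        b = a.copy()
        zeros = np.argwhere(np.triu(b, 1) == 0)
        u, v = zeros[0]
        b[u, v] = b[v, u] = 1
        assert connectivity(b, 0, targets) >= c0


class TestConnectivityP:
    def test_determinism(self, rng):
        a = random_adjacency(rng, 30)
        r1 = connectivity_p(a, 0, [3, 4, 5], draws=50, rng=7)
        r2 = connectivity_p(a, 0, [3, 4, 5], draws=50, rng=7)
        assert r1.p_value == r2.p_value and (r1.null_counts == r2.null_counts).all()

    def test_planted_neighborhood_is_significant(self, rng):
        # sparse graph; targets = the full 2-hop neighborhood of node 0
        a = random_adjacency(rng, 120, p=0.04)
        reach = two_hop_reachable(a, 0)
        targets = list(np.flatnonzero(reach))
        assert len(targets) >= 3  # sparse but non-degenerate neighbourhood
        res = connectivity_p(a, 0, targets, draws=500, rng=11)
        assert res.c == len(targets)
        assert res.p_value <= 0.05


class TestWeightedKuiper:
    def test_exponent_zero_recovers_classic_kuiper(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            r = np.sort(rng.normal(size=n))[::-1]
            member = rng.random(n) < 0.3
            if member.all() or not member.any():
                continue
            got = weighted_kuiper(r, member, weight_exponent=0.0)
            # direct two-sample ECDF scan oracle on the rank positions
            xm = np.flatnonzero(member)
            xn = np.flatnonzero(~member)
            grid = np.arange(n)
            fm = np.searchsorted(xm, grid, side="right") / len(xm)
            fn = np.searchsorted(xn, grid, side="right") / len(xn)
            d_pos = max(0.0, np.max(fm - fn))
            d_neg = max(0.0, np.max(fn - fm))
            assert got == pytest.approx(d_pos + d_neg, abs=1e-12)

    def test_top_block_hand_computation(self):
        # members hold the top 2 of 6 ranks with equal |r|: full separation
        r = np.array([0.9, 0.9, 0.5, 0.4, 0.3, 0.2])
        member = np.array([True, True, False, False, False, False])
        assert weighted_kuiper(r, member, 1.0) == pytest.approx(1.0)

    def test_interleaved_below_extreme_placement(self):
        r = np.linspace(1, -1, 10)
        interleaved = np.array([True, False] * 5)
        extreme = np.array([True] * 5 + [False] * 5)
        assert weighted_kuiper(r, interleaved, 1.0) <= weighted_kuiper(r, extreme, 1.0)

    def test_zero_member_weights_fall_back_to_uniform(self):
        r = np.array([0.5, 0.2, 0.0, 0.0, -0.3])
        member = np.array([False, False, True, True, False])
        with pytest.warns(UserWarning, match="uniform"):
            got = weighted_kuiper(r, member, 1.0)
        assert got == pytest.approx(weighted_kuiper(r, member, 0.0))

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            weighted_kuiper(
                np.array([0.1, 0.5]), np.array([True, False]), 1.0
            )


class TestLeadingEdges:
    def test_top_block_members(self):
        r = np.array([0.9, 0.8, 0.5, 0.1, -0.2, -0.4])
        member = np.array([True, True, False, False, False, False])
        pos, neg = leading_edges(r, member, list("ABCDEF"))
        assert pos == {"A", "B"} and neg == frozenset()

    def test_single_member_lands_in_exactly_one_subset(self):
        r = np.linspace(0.9, -0.9, 7)
        for position in range(7):
            member = np.zeros(7, dtype=bool)
            member[position] = True
            pos, neg = leading_edges(r, member, [f"g{i}" for i in range(7)])
            assert len(pos) + len(neg) == 1

    def test_bimodal_plant_gives_disjoint_nonempty_subsets(self):
        r = np.array([0.95, 0.9, 0.4, 0.1, -0.1, -0.4, -0.88, -0.93])
        member = np.array([True, True, False, False, False, False, True, True])
        pos, neg = leading_edges(r, member, [f"g{i}" for i in range(8)])
        assert pos == {"G0", "G1"} and neg == {"G6", "G7"}


class TestKuiperP:
    def _expr(self, seed=13):
        spec = ScenarioSpec(
            seed=seed, universe_size=60, effect_sign_mode="none",
            compartments=("crypt",),
        )
        genes = [f"NG{i}" for i in range(5)]
        expr, _ = make_expression(spec, genes)
        return expr

    def test_determinism(self):
        expr = self._expr()
        universe = sorted(expr.genes)
        ts = GeneSet("t", frozenset(universe[10:20]))
        r1 = kuiper_p(expr, universe, ts, universe[0], n_null_sets=50, rng=5)
        r2 = kuiper_p(expr, universe, ts, universe[0], n_null_sets=50, rng=5)
        assert (r1.K, r1.null_mu, r1.null_sigma, r1.p_value) == (
            r2.K, r2.null_mu, r2.null_sigma, r2.p_value
        )

    def test_bimodal_plant_is_significant(self):
        expr = self._expr()
        universe = sorted(expr.genes)
        node = universe[0]
        from perturbnet.expr_stats import spearman_matrix

        r = spearman_matrix(expr, [node], [g for g in universe if g != node])
        ranked = r.iloc[0].sort_values()
        plant = set(ranked.index[:6]) | set(ranked.index[-6:])
        res = kuiper_p(expr, universe, GeneSet("plant", frozenset(plant)), node,
                       n_null_sets=200, rng=3)
        assert res.p_value < 0.01
        assert res.leading_pos and res.leading_neg
        assert not (res.leading_pos & res.leading_neg)

    def test_target_outside_universe_rejected(self):
        expr = self._expr()
        universe = sorted(expr.genes)
        with pytest.raises(ValueError, match="universe"):
            kuiper_p(expr, universe, GeneSet("t", frozenset({"NOT_A_GENE"})),
                     universe[0], n_null_sets=10, rng=0)


class TestDeNodes:
    def _expr_with_planted_gene(self):
        rng = np.random.default_rng(77)
        probes = {}
        genes = {}
        for g in [f"g{i}" for i in range(6)]:
            mut = list(rng.normal(size=4))
            wt = list(rng.normal(size=4))
            if g == "g0":  # huge planted shift
                mut = [m + 50.0 for m in mut]
            probes[f"{g}_p1"] = {("MUT", "crypt"): mut, ("WT", "crypt"): wt}
            genes[f"{g}_p1"] = g
        return build_expression(probes, genes, genotypes=["MUT", "WT"])

    def test_planted_gene_included(self):
        expr = self._expr_with_planted_gene()
        design = PerturbationDesign("MUT", "WT", "crypt")
        hits = de_nodes(expr, [design], [f"g{i}" for i in range(6)], alpha=0.05)
        assert "G0" in hits

    def test_alpha_one_selects_everything(self):
        expr = self._expr_with_planted_gene()
        design = PerturbationDesign("MUT", "WT", "crypt")
        hits = de_nodes(expr, [design], [f"g{i}" for i in range(6)], alpha=1.0)
        assert len(hits) == 6

    def test_null_selection_rate_is_nominal(self):
        rng = np.random.default_rng(5)
        count, total = 0, 0
        for _ in range(20):
            probes = {
                f"g{i}_p1": {
                    ("MUT", "crypt"): list(rng.normal(size=4)),
                    ("WT", "crypt"): list(rng.normal(size=4)),
                }
                for i in range(10)
            }
            expr = build_expression(
                probes, {f"g{i}_p1": f"g{i}" for i in range(10)},
                genotypes=["MUT", "WT"],
            )
            design = PerturbationDesign("MUT", "WT", "crypt")
            hits = de_nodes(expr, [design], [f"g{i}" for i in range(10)], alpha=0.05)
            count += len(hits)
            total += 10
        # |t| > z threshold at df≈6 is anti-conservative vs the normal cutoff,
        # but the rate should stay well below a handful per ten genes
        assert count / total < 0.35
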