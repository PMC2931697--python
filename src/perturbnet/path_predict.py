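"""Candidate path enumeration, scoring and merging into a driver-gene network.

Given a filtered/augmented interaction network and two driver genes, the
predictor enumerates all simple source→sink paths of bounded length (up to 6
nodes including the endpoints), scores each path by

* the mean Pearson coexpression over consecutive gene pairs, and
* the support of Gene Ontology association rules mined from reference
  pathways: for every consecutive pair, the maximum rule confidence over
  the pair's annotation-term combinations, averaged along the path,

and keeps the paths that clear the coexpression threshold and whose rule
score exceeds the (1 − alpha) quantile of an empirical null built from
random simple paths of matched length. The union of the surviving paths'
edges is the predicted subnetwork, retaining each edge's observed/inferred
origin label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .expr_stats import ExpressionMatrix, gene_correlation
from .graph_core import Network, _norm

__all__ = [
    "GoRuleSet",
    "PathCandidate",
    "mine_go_rules",
    "enumerate_paths",
    "path_coexpression",
    "rule_score",
    "score_paths",
    "filter_and_merge",
]


@dataclass
class GoRuleSet:
    """Association rules over ordered GO-term pairs.

    ``rules[(g1, g2)] = (support, confidence)`` where support counts pathway
    edges whose endpoints are annotated g1 and g2, and confidence divides by
    the number of pathway proteins annotated with the antecedent term g1.
    """

    rules: dict[tuple[str, str], tuple[int, float]] = field(default_factory=dict)

    def confidence(self, g1: str, g2: str) -> float:
        return self.rules.get((g1, g2), (0, 0.0))[1]

    def __len__(self) -> int:
        return len(self.rules)


@dataclass
class PathCandidate:
    """A simple source→sink path with its two scores (NaN until computed)."""

    nodes: tuple[str, ...]
    avg_coexpression: float = float("nan")
    rule_score: float = float("nan")
    scorable: bool = True

    def __post_init__(self) -> None:
        self.nodes = tuple(_norm(n) for n in self.nodes)
        if len(self.nodes) < 2:
            raise ValueError("a path needs at least two nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("paths must be simple (no repeated nodes)")

    @property
    def edges(self) -> list[frozenset[str]]:
        return [
            frozenset((self.nodes[i], self.nodes[i + 1]))
            for i in range(len(self.nodes) - 1)
        ]


def mine_go_rules(
    pathway_edges: list[tuple[str, str]],
    annotations: dict[str, frozenset[str]],
) -> GoRuleSet:
    """Mine GO-term association rules from reference pathway edges.

    For each pathway edge (u, v) and each annotation pair (g_u, g_v), support
    of the ordered rule (g_u, g_v) is incremented; since pathway edges are
    undirected, both orientations are counted. Confidence normalizes support
    by the number of distinct pathway proteins annotated with the antecedent
    term.
    """
    annotations = {_norm(g): frozenset(t) for g, t in annotations.items()}
    if not annotations:
        warnings.warn("empty annotation map; rule set will be empty", stacklevel=2)
        return GoRuleSet()
    pathway_proteins: set[str] = set()
    for u, v in pathway_edges:
        pathway_proteins.update((_norm(u), _norm(v)))
    term_count: dict[str, int] = {}
    for protein in pathway_proteins:
        for term in annotations.get(protein, frozenset()):
            term_count[term] = term_count.get(term, 0) + 1
    support: dict[tuple[str, str], int] = {}
    for u, v in pathway_edges:
        u, v = _norm(u), _norm(v)
        for gu in annotations.get(u, frozenset()):
            for gv in annotations.get(v, frozenset()):
                support[(gu, gv)] = support.get((gu, gv), 0) + 1
                if (gu, gv) != (gv, gu):
                    support[(gv, gu)] = support.get((gv, gu), 0) + 1
    rules = {
        pair: (count, count / term_count[pair[0]])
        for pair, count in support.items()
    }
    return GoRuleSet(rules=rules)


def enumerate_paths(
    net: Network, source: str, sink: str, max_nodes: int = 6
) -> list[PathCandidate]:
    """All simple source→sink paths with at most ``max_nodes`` nodes.

    Output order is deterministic (lexicographic by node sequence). A
    disconnected pair yields an empty list.
    """
    source, sink = _norm(source), _norm(sink)
    if source == sink:
        raise ValueError("source and sink must differ")
    for node in (source, sink):
        if node not in net:
            raise KeyError(f"node {node!r} not in network")
    if max_nodes < 2:
        raise ValueError("max_nodes must be at least 2")
    paths = [
        tuple(p)
        for p in nx.all_simple_paths(net.graph, source, sink, cutoff=max_nodes - 1)
    ]
    return [PathCandidate(nodes=p) for p in sorted(paths)]


def path_coexpression(path: PathCandidate, expr: ExpressionMatrix) -> float:
    """Mean Pearson coexpression over consecutive gene pairs along the path.

    A path containing a gene with no probe is flagged un-scorable
    (``path.scorable = False``) and returns NaN; it is excluded downstream.
    """
    if any(not expr.has_gene(g) for g in path.nodes):
        path.scorable = False
        path.avg_coexpression = float("nan")
        return path.avg_coexpression
    corrs = [
        gene_correlation(expr, path.nodes[i], path.nodes[i + 1], method="pearson")
        for i in range(len(path.nodes) - 1)
    ]
    path.avg_coexpression = float(np.mean(corrs))
    return path.avg_coexpression


def rule_score(
    path: PathCandidate,
    rules: GoRuleSet,
    annotations: dict[str, frozenset[str]],
) -> float:
    """Mean over consecutive pairs of the best matching rule confidence.

    For each consecutive pair, the maximum confidence over all annotation
    term pairs of the endpoints (0 when no rule matches or a gene is
    unannotated).
    """
    annotations = {_norm(g): frozenset(t) for g, t in annotations.items()}
    pair_scores = []
    for i in range(len(path.nodes) - 1):
        u, v = path.nodes[i], path.nodes[i + 1]
        best = 0.0
        for gu in annotations.get(u, frozenset()):
            for gv in annotations.get(v, frozenset()):
                best = max(best, rules.confidence(gu, gv), rules.confidence(gv, gu))
        pair_scores.append(best)
    path.rule_score = float(np.mean(pair_scores))
    return path.rule_score


def score_paths(
    paths: list[PathCandidate],
    expr: ExpressionMatrix,
    rules: GoRuleSet | None = None,
    annotations: dict[str, frozenset[str]] | None = None,
) -> list[PathCandidate]:
    """Fill avg_coexpression (and rule_score) for many paths at once.

    Equivalent to calling :func:`path_coexpression` and :func:`rule_score`
    per path, but the pairwise Pearson correlations of representative probes
    are computed in one matrix operation.
    """
    from .expr_stats import max_intensity_probe

    genes = sorted({g for p in paths for g in p.nodes})
    present = [g for g in genes if expr.has_gene(g)]
    profile = np.array(
        [expr.values.loc[max_intensity_probe(expr, g)].to_numpy() for g in present]
    )
    idx = {g: i for i, g in enumerate(present)}
    if len(present) >= 2:
        sd = profile.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(profile)
        corr = np.nan_to_num(corr, nan=0.0)
        for i in range(len(present)):
            if sd[i] == 0:
                corr[i, :] = 0.0
                corr[:, i] = 0.0
                corr[i, i] = 1.0
    else:
        corr = np.ones((len(present), len(present)))
    for p in paths:
        if any(g not in idx for g in p.nodes):
            p.scorable = False
            p.avg_coexpression = float("nan")
        else:
            p.avg_coexpression = float(
                np.mean(
                    [
                        corr[idx[p.nodes[i]], idx[p.nodes[i + 1]]]
                        for i in range(len(p.nodes) - 1)
                    ]
                )
            )
        if rules is not None and annotations is not None:
            rule_score(p, rules, annotations)
    return paths


def _random_simple_path(
    g: nx.Graph, n_nodes: int, rng: np.random.Generator, max_tries: int = 50
) -> tuple[str, ...] | None:
    """One uniform-start random simple path with exactly ``n_nodes`` nodes."""
    nodes = sorted(g.nodes())
    for _ in range(max_tries):
        path = [nodes[rng.integers(len(nodes))]]
        while len(path) < n_nodes:
            options = [n for n in g.neighbors(path[-1]) if n not in path]
            if not options:
                break
            path.append(sorted(options)[rng.integers(len(options))])
        if len(path) == n_nodes:
            return tuple(path)
    return None


def filter_and_merge(
    paths: list[PathCandidate],
    net: Network,
    coexpr_threshold: float = 0.5,
    alpha: float = 0.01,
    null_paths: int = 1000,
    rng: np.random.Generator | int | None = None,
    rules: GoRuleSet | None = None,
    annotations: dict[str, frozenset[str]] | None = None,
) -> tuple[Network, list[PathCandidate]]:
    """Keep significant, coexpressed paths and merge their edges.

    A path survives iff (a) it is scorable, (b) its average coexpression is
    at least ``coexpr_threshold``, and (c) its rule score exceeds the
    (1 − alpha) quantile of an empirical null of rule scores over
    ``null_paths`` random simple paths of the same length drawn from ``net``
    (with alpha >= 1 the rule-score test is waived). Returns the merged
    subnetwork — edges keep their observed/inferred origin — and the list of
    surviving paths.
    """
    rng = np.random.default_rng(rng)
    if rules is None or annotations is None:
        if not (alpha >= 1.0 or all(np.isfinite(p.rule_score) for p in paths)):
            raise ValueError(
                "rule scores missing: supply rules+annotations or pre-score paths"
            )
    scored = [p for p in paths if p.scorable and np.isfinite(p.avg_coexpression)]
    # empirical null of rule scores, one per path length present
    thresholds: dict[int, float] = {}
    if alpha < 1.0:
        g = net.graph
        for length in sorted({len(p.nodes) for p in scored}):
            null_scores = np.zeros(null_paths)
            for i in range(null_paths):
                rp = _random_simple_path(g, length, rng)
                if rp is None:
                    continue
                cand = PathCandidate(nodes=rp)
                if rules is not None and annotations is not None:
                    null_scores[i] = rule_score(cand, rules, annotations)
            thresholds[length] = float(np.quantile(null_scores, 1.0 - alpha))
    kept: list[PathCandidate] = []
    for p in scored:
        if p.avg_coexpression < coexpr_threshold:
            continue
        if alpha < 1.0:
            if not np.isfinite(p.rule_score):
                raise ValueError(f"path {p.nodes} has no rule score")
            if p.rule_score <= thresholds[len(p.nodes)]:
                continue
        kept.append(p)
    merged = Network()
    if not kept:
        warnings.warn("no paths survive filtering; returning empty network",
                      stacklevel=2)
        return merged, kept
    for p in kept:
        for node in p.nodes:
            merged.add_node(node)
        for edge in p.edges:
            u, v = sorted(edge)
            if merged.has_edge(u, v):
                continue
            origin, rec = net.edge_data(u, v)
            merged.add_edge(u, v, origin=origin, evidence=rec)
    return merged, kept
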