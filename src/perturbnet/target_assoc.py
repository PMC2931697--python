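"""Associating proteomic target sets with network nodes.

Proteomic screens (e.g. 2D-DIGE followed by mass spectrometry) measure a
modest, biased slice of the proteome that rarely overlaps a candidate
network directly. Two relational maps connect the two:

* **Physical proximity** — a network node i is linked to a measured protein
  k when a 2-hop path i–j–k exists in the global interaction network
  (indicator D2(i, k)); the node's connectivity to a target set is
  C_i = Σ_k D2(i, k), tested against an empirical null of equally sized
  random protein sets.

* **Coexpression** — the distribution of correlation coefficients between a
  node and the target genes is compared with the node's correlations to the
  whole expression universe using a weighted Kuiper statistic. Kuiper's
  K = D⁺ + D⁻ sums the maximal positive and negative CDF deviations, which
  makes it sensitive to bimodal shifts — coregulated groups are expected to
  contain both positively and negatively correlated members. Following the
  GSEA weighting scheme, member steps are proportional to |r|^exponent
  (exponent 0 recovers the classic unweighted Kuiper statistic). The null is
  an MLE normal fit to K over random same-size gene sets, and leading-edge
  subsets (the members driving each deviation) are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expr_stats import ExpressionMatrix, PerturbationDesign, welch_t, max_intensity_probe, spearman_matrix
from .graph_core import GeneSet, _norm

__all__ = [
    "ProximityResult",
    "KuiperResult",
    "two_hop",
    "two_hop_reachable",
    "connectivity",
    "connectivity_p",
    "weighted_kuiper",
    "kuiper_p",
    "leading_edges",
    "de_nodes",
]


@dataclass
class ProximityResult:
    """2-hop connectivity of one node to a target set, with empirical null."""

    node: str
    c: int
    null_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        self.null_counts = np.asarray(self.null_counts, dtype=int)
        if self.c < 0:
            raise ValueError("connectivity must be nonnegative")


@dataclass
class KuiperResult:
    """Weighted Kuiper test of one node's coexpression with a target set."""

    node: str
    genes: list[str]  # universe genes in descending-correlation order
    r: np.ndarray  # the ordered correlation vector
    K: float
    null_mu: float
    null_sigma: float
    p_value: float
    leading_pos: frozenset[str]
    leading_neg: frozenset[str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.K < 0:
            raise ValueError("K must be nonnegative")


# ---------------------------------------------------------------------------
# physical proximity
# ---------------------------------------------------------------------------


def two_hop(a: np.ndarray, i: int, k: int) -> int:
    """1 iff some intermediate j ∉ {i, k} has A[i][j] = A[j][k] = 1."""
    if i == k:
        raise ValueError("two_hop is undefined for i == k")
    row_i = np.asarray(a[i], dtype=bool).copy()
    col_k = np.asarray(a[:, k], dtype=bool).copy()
    row_i[[i, k]] = False
    col_k[[i, k]] = False
    return int(bool(np.any(row_i & col_k)))


def two_hop_reachable(a: np.ndarray, i: int) -> np.ndarray:
    """Boolean vector over nodes k: is k 2-hop reachable from i?

    With a hollow symmetric adjacency matrix the intermediate j is
    automatically distinct from both endpoints, so this equals the boolean
    of (A²)[i, :] > 0 with the diagonal entry cleared.
    """
    a = np.asarray(a)
    reach = (a[i].astype(np.int64) @ a) > 0
    reach[i] = False
    return reach


def connectivity(a: np.ndarray, i: int, target_idx) -> int:
    """C_i = number of targets that are 2-hop reachable from node i.

    ``target_idx`` holds node indices; index i itself is ignored if present.
    """
    target_idx = np.asarray(sorted(set(int(t) for t in target_idx) - {int(i)}))
    if target_idx.size == 0:
        raise ValueError("target set is empty")
    reach = two_hop_reachable(a, i)
    return int(np.sum(reach[target_idx]))


def connectivity_p(
    a: np.ndarray,
    i: int,
    target_idx,
    draws: int = 10000,
    rng: np.random.Generator | int | None = None,
    node_label: str = "",
) -> ProximityResult:
    """Connectivity with an empirical null of random same-size protein sets.

    Null sets are drawn uniformly (without replacement) from all network
    nodes except the query node; p is the add-one-smoothed upper tail.
    """
    rng = np.random.default_rng(rng)
    target_idx = sorted(set(int(t) for t in target_idx) - {int(i)})
    n = len(target_idx)
    if n == 0:
        raise ValueError("target set is empty")
    universe = np.array([j for j in range(a.shape[0]) if j != i])
    if universe.size < n:
        raise ValueError("universe smaller than the target set")
    reach = two_hop_reachable(a, i)
    c = int(np.sum(reach[np.asarray(target_idx)]))
    null_counts = np.empty(draws, dtype=int)
    for d in range(draws):
        draw = rng.choice(universe, size=n, replace=False)
        null_counts[d] = int(np.sum(reach[draw]))
    p = (1 + int(np.sum(null_counts >= c))) / (draws + 1)
    return ProximityResult(
        node=node_label or str(i), c=c, null_counts=null_counts, p_value=p
    )


# ---------------------------------------------------------------------------
# weighted Kuiper coexpression test
# ---------------------------------------------------------------------------


def _kuiper_scan(
    r: np.ndarray, member: np.ndarray, weight_exponent: float
) -> tuple[float, np.ndarray]:
    """Running CDF-difference scan; returns (K, gap vector).

    ``r`` must be sorted in descending order; ``member`` flags target genes.
    The sample CDF steps |r|^exponent at members (normalized to sum 1), the
    control CDF steps uniformly at non-members. gap[m] is
    F_sample − F_control after processing element m.
    """
    r = np.asarray(r, dtype=float)
    member = np.asarray(member, dtype=bool)
    if r.shape != member.shape:
        raise ValueError("r and membership flags must align")
    if np.any(np.diff(r) > 0):
        raise ValueError("r must be sorted in descending order")
    n_mem = int(member.sum())
    n_non = int((~member).sum())
    if n_mem == 0 or n_non == 0:
        raise ValueError("need at least one member and one non-member")
    weights = np.where(member, np.abs(r) ** weight_exponent, 0.0)
    total = weights.sum()
    if total == 0.0:
        warnings.warn(
            "all member correlations are zero; falling back to uniform weights",
            stacklevel=3,
        )
        weights = member.astype(float)
        total = float(n_mem)
    sample_steps = weights / total
    control_steps = (~member) / n_non
    gaps = np.cumsum(sample_steps - control_steps)
    d_pos = max(0.0, float(gaps.max()))
    d_neg = max(0.0, float(-gaps.min()))
    return d_pos + d_neg, gaps


def weighted_kuiper(
    r: np.ndarray, member: np.ndarray, weight_exponent: float = 1.0
) -> float:
    """Weighted Kuiper statistic K = D⁺ + D⁻ between member and non-member CDFs.

    With ``weight_exponent=0`` this is the classic two-sample Kuiper
    statistic on ranks.
    """
    k, _ = _kuiper_scan(r, member, weight_exponent)
    return k


def leading_edges(
    r: np.ndarray,
    member: np.ndarray,
    genes: list[str],
    weight_exponent: float = 1.0,
) -> tuple[frozenset[str], frozenset[str]]:
    """Member genes driving the two extreme CDF deviations.

    ``leading_pos`` holds members at or before the position of the maximal
    positive deviation; ``leading_neg`` holds members after the position of
    the maximal negative deviation. A member qualifying for both (possible
    only when the two extreme positions bracket it) is assigned to the side
    with the larger deviation, so singleton target sets land in exactly one
    subset.
    """
    _, gaps = _kuiper_scan(r, member, weight_exponent)
    member = np.asarray(member, dtype=bool)
    genes = [_norm(g) for g in genes]
    d_pos = float(gaps.max())
    d_neg = float(-gaps.min())
    pos: set[str] = set()
    neg: set[str] = set()
    if d_pos > 0:
        pos_cut = int(np.argmax(gaps))  # first occurrence
        pos = {g for m, (g, flag) in enumerate(zip(genes, member)) if flag and m <= pos_cut}
    if d_neg > 0:
        neg_cut = len(gaps) - 1 - int(np.argmin(gaps[::-1]))  # last occurrence
        neg = {g for m, (g, flag) in enumerate(zip(genes, member)) if flag and m > neg_cut}
    both = pos & neg
    if both:
        if d_pos >= d_neg:
            neg -= both
        else:
            pos -= both
    return frozenset(pos), frozenset(neg)


def kuiper_p(
    expr: ExpressionMatrix,
    universe,
    targets: GeneSet,
    node: str,
    n_null_sets: int = 500,
    weight_exponent: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> KuiperResult:
    """Weighted Kuiper test of one node's coexpression with a target set.

    ``r`` collects the Spearman correlations (representative probes, all
    samples) between ``node`` and every universe gene except the node
    itself. The null is K over ``n_null_sets`` random same-size gene sets;
    a normal distribution is fit by maximum likelihood and p is its upper
    tail.
    """
    rng = np.random.default_rng(rng)
    node = _norm(node)
    universe = sorted({_norm(g) for g in universe} - {node})
    members = set(targets.members) - {node}
    if not members <= set(universe):
        raise ValueError("target set must be contained in the universe")
    if not members:
        raise ValueError("target set is empty after removing the node itself")
    corr = spearman_matrix(expr, [node], universe)
    r_raw = corr.to_numpy()[0]
    order = np.argsort(-r_raw, kind="stable")
    r = r_raw[order]
    genes_sorted = [universe[j] for j in order]
    member_flags = np.array([g in members for g in genes_sorted])
    k_obs = weighted_kuiper(r, member_flags, weight_exponent)
    n = int(member_flags.sum())
    n_univ = len(genes_sorted)
    null_k = np.empty(n_null_sets)
    for s in range(n_null_sets):
        idx = rng.choice(n_univ, size=n, replace=False)
        flags = np.zeros(n_univ, dtype=bool)
        flags[idx] = True
        null_k[s] = weighted_kuiper(r, flags, weight_exponent)
    mu = float(null_k.mean())
    sigma = float(null_k.std(ddof=0))  # MLE fit
    if sigma == 0.0:
        raise ValueError("degenerate Kuiper null (zero variance)")
    p = float(stats.norm.sf(k_obs, loc=mu, scale=sigma))
    pos, neg = leading_edges(r, member_flags, genes_sorted, weight_exponent)
    return KuiperResult(
        node=node,
        genes=genes_sorted,
        r=r,
        K=k_obs,
        null_mu=mu,
        null_sigma=sigma,
        p_value=p,
        leading_pos=pos,
        leading_neg=neg,
    )


# ---------------------------------------------------------------------------
# differentially expressed node selection
# ---------------------------------------------------------------------------


def de_nodes(
    expr: ExpressionMatrix,
    designs: list[PerturbationDesign],
    genes,
    alpha: float = 0.05,
) -> frozenset[str]:
    """Genes whose representative probe is differentially expressed.

    A gene qualifies when the unequal-variance t of its maximum-intensity
    probe satisfies |t| > Φ⁻¹(1 − alpha/2) in at least one of the supplied
    contrasts (typically one design per mutant per tissue compartment). A
    gene excluded by a particular design is simply not evaluated there.
    """
    threshold = stats.norm.ppf(1.0 - alpha / 2.0)
    selected: set[str] = set()
    genes = sorted({_norm(g) for g in genes})
    for design in designs:
        mut_cols = expr.samples_where(design.mutant_label, design.compartment)
        wt_cols = expr.samples_where(design.wt_label, design.compartment)
        if len(mut_cols) < 2 or len(wt_cols) < 2:
            raise ValueError(
                f"contrast {design.mutant_label}/{design.compartment}"
                " lacks replicates"
            )
        for gene in genes:
            if gene in design.excluded_genes or not expr.has_gene(gene):
                continue
            probe = max_intensity_probe(expr, gene)
            t, _, _ = welch_t(
                expr.values.loc[probe, mut_cols].to_numpy()[None, :],
                expr.values.loc[probe, wt_cols].to_numpy()[None, :],
            )
            if abs(float(t[0])) > threshold:
                selected.add(gene)
    return frozenset(selected)
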