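"""The V² joint-perturbation statistic and its permutation machinery.

To ask whether a candidate gene network is *jointly* differentially
expressed under two independent perturbations (e.g. two mutant mouse lines,
each contrasted against wild type), Hotelling's T² is extended across
experiments: with off-diagonal covariances set to zero (sample covariance
matrices at these group sizes are singular), the statistic reduces to

    V² = Σ_i  t_i^(A) · t_i^(B)

the sum over network probes of the product of the two experiments' scaled
t-statistics. Unlike T², V² is signed: it is large and positive when the two
perturbations move the network genes in the same direction, and negative for
opposed effects. A self-pair (A = B) recovers Σ t² — a scaled
diagonal-covariance Hotelling T².

Significance comes from a permutation null: group labels are reshuffled
within each experiment independently (preserving group sizes), and because
the groups are small, per-probe Gaussian noise — with SD estimated from each
probe's sample SD within its genetic background — is added to every permuted
matrix to smooth and interpolate the null. t is scale-self-normalizing, so
the added noise widens nothing systematically; it fills the gaps of the
small discrete permutation space. The positive tail is used when the
perturbations are expected to act in the same direction; the negative tail
mirrors it for antagonistic pairs.

For k perturbations, all pairwise statistics form a k×k matrix whose
diagonal carries within-experiment significance and whose off-diagonal
entries carry joint support; off-diagonal p-values can be aggregated by
Fisher's method when k > 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expr_stats import (
    ExpressionMatrix,
    PerturbationDesign,
    TStatVector,
    contrast_t,
    welch_t,
)
from .graph_core import _norm

__all__ = [
    "V2Result",
    "V2Matrix",
    "AggregateResult",
    "v2",
    "permutation_null",
    "tail_p",
    "v2_test",
    "v2_matrix",
    "fisher_tau",
    "binomial_exceedance",
]


@dataclass
class V2Result:
    """Observed V², its permutation null sample, and the tail p-value."""

    observed: float
    null_sample: np.ndarray
    p_value: float
    tail: str

    def __post_init__(self) -> None:
        self.null_sample = np.asarray(self.null_sample, dtype=float)
        if self.tail not in ("positive", "negative"):
            raise ValueError("tail must be 'positive' or 'negative'")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


@dataclass
class V2Matrix:
    """Pairwise V² statistics and p-values for k experiments."""

    labels: list[str]
    stats: pd.DataFrame
    p_values: pd.DataFrame

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.stats.shape != (k, k) or self.p_values.shape != (k, k):
            raise ValueError("stat and p-value matrices must be k × k")

    def off_diagonal_p(self) -> list[float]:
        """Upper-triangle off-diagonal p-values (joint support terms)."""
        out = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                out.append(float(self.p_values.iloc[i, j]))
        return out


@dataclass
class AggregateResult:
    """Fisher's method: τ = −2 Σ ln p against χ² with 2n degrees of freedom."""

    tau: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.df <= 0 or self.df % 2 != 0:
            raise ValueError("df must be an even positive integer")


def v2(t_a: TStatVector, t_b: TStatVector) -> float:
    """Σ_i t_a[i] · t_b[i] over the shared probe list.

    The two vectors must be computed on the identical probe list (same gene
    universe, same exclusions).
    """
    if t_a.probes != t_b.probes:
        raise ValueError("t-statistic vectors are not aligned on the same probes")
    return float(np.dot(t_a.t, t_b.t))


def _experiment_arrays(
    expr: ExpressionMatrix,
    design: PerturbationDesign,
    probes: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """(mutant, wt) intensity arrays for the design's compartment."""
    mut_cols = expr.samples_where(design.mutant_label, design.compartment)
    wt_cols = expr.samples_where(design.wt_label, design.compartment)
    if len(mut_cols) < 2 or len(wt_cols) < 2:
        raise ValueError("each group needs at least 2 replicates to permute")
    mut = expr.values.loc[probes, mut_cols].to_numpy(dtype=float)
    wt = expr.values.loc[probes, wt_cols].to_numpy(dtype=float)
    return mut, wt


def _shared_probes(
    exprs: list[ExpressionMatrix],
    designs: list[PerturbationDesign],
    genes,
) -> list[str]:
    """Probe list shared by all experiments after pooled gene exclusions."""
    excluded: set[str] = set()
    for d in designs:
        excluded |= set(d.excluded_genes)
    kept = sorted({_norm(g) for g in genes} - excluded)
    probes: list[str] = []
    for gene in kept:
        if all(e.has_gene(gene) for e in exprs):
            probes.extend(exprs[0].probes_for(gene))
    if not probes:
        raise ValueError("no probes remain after exclusions")
    return probes


def _permuted_t(
    pooled: np.ndarray,
    n_mut: int,
    noise_sd: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One permutation draw of the Welch t vector with smoothing noise."""
    order = rng.permutation(pooled.shape[1])
    shuffled = pooled[:, order] + rng.normal(size=pooled.shape) * noise_sd[:, order]
    t, _, _ = welch_t(shuffled[:, :n_mut], shuffled[:, n_mut:])
    return t


def permutation_null(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    design_a: PerturbationDesign,
    design_b: PerturbationDesign,
    genes,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Smoothed permutation null sample of V² for one experiment pair.

    Per permutation, phenotype labels are reshuffled within each experiment
    independently (group sizes preserved) and per-entry Gaussian noise is
    added, with SD equal to the probe's sample SD within the sample's
    original genetic background; both t vectors and V² are recomputed. When
    the two experiments are the same object, a single relabeling drives both
    sides, giving the null of the within-experiment statistic Σ t².
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(rng)
    probes = _shared_probes([expr_a, expr_b], [design_a, design_b], genes)
    mut_a, wt_a = _experiment_arrays(expr_a, design_a, probes)
    mut_b, wt_b = _experiment_arrays(expr_b, design_b, probes)
    same = expr_a is expr_b and design_a == design_b

    def _pooled(mut: np.ndarray, wt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pooled = np.hstack([mut, wt])
        sd = np.hstack(
            [
                np.repeat(mut.std(axis=1, ddof=1)[:, None], mut.shape[1], axis=1),
                np.repeat(wt.std(axis=1, ddof=1)[:, None], wt.shape[1], axis=1),
            ]
        )
        return pooled, sd

    pooled_a, sd_a = _pooled(mut_a, wt_a)
    pooled_b, sd_b = _pooled(mut_b, wt_b)
    null = np.empty(n_perm)
    for i in range(n_perm):
        t_a = _permuted_t(pooled_a, mut_a.shape[1], sd_a, rng)
        t_b = t_a if same else _permuted_t(pooled_b, mut_b.shape[1], sd_b, rng)
        null[i] = float(np.dot(t_a, t_b))
    return null


def tail_p(null: np.ndarray, observed: float, tail: str = "positive") -> float:
    """Add-one-smoothed empirical tail probability.

    Positive tail: (1 + #{null >= observed}) / (n + 1); the negative tail
    mirrors it. The add-one correction keeps p strictly positive even when
    the observed statistic exceeds every null draw.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null sample is empty")
    if tail == "positive":
        exceed = int(np.sum(null >= observed))
    elif tail == "negative":
        exceed = int(np.sum(null <= observed))
    else:
        raise ValueError("tail must be 'positive' or 'negative'")
    return (1 + exceed) / (null.size + 1)


def v2_test(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    design_a: PerturbationDesign,
    design_b: PerturbationDesign,
    genes,
    n_perm: int = 10000,
    tail: str = "positive",
    rng: np.random.Generator | int | None = None,
) -> V2Result:
    """Observed V² for one experiment pair with its permutation p-value."""
    excluded = set(design_a.excluded_genes) | set(design_b.excluded_genes)
    t_a = contrast_t(expr_a, design_a, genes, extra_excluded=excluded)
    t_b = contrast_t(expr_b, design_b, genes, extra_excluded=excluded)
    observed = v2(t_a, t_b)
    null = permutation_null(
        expr_a, expr_b, design_a, design_b, genes, n_perm=n_perm, rng=rng
    )
    return V2Result(
        observed=observed,
        null_sample=null,
        p_value=tail_p(null, observed, tail),
        tail=tail,
    )


def v2_matrix(
    experiments: list[tuple[ExpressionMatrix, PerturbationDesign]],
    genes,
    n_perm: int = 10000,
    tail: str = "positive",
    rng: np.random.Generator | int | None = None,
) -> V2Matrix:
    """All pairwise V² statistics and p-values for k experiments.

    Exclusions are pooled across all designs so every entry shares one probe
    list. The diagonal is the within-experiment Σ t² (each with its own
    single-experiment permutation null); each off-diagonal entry gets its
    own joint permutation null. Child RNG streams are split per matrix cell
    so results are reproducible regardless of evaluation order.
    """
    if len(experiments) < 2:
        raise ValueError("need at least 2 experiments")
    seed_seq = np.random.SeedSequence(
        rng if isinstance(rng, (int, np.integer)) else None
    )
    if isinstance(rng, np.random.Generator):
        # derive a stable splitting seed from the generator
        seed_seq = np.random.SeedSequence(int(rng.integers(2**31)))
    labels = [d.mutant_label for _, d in experiments]
    excluded: set[str] = set()
    for _, d in experiments:
        excluded |= set(d.excluded_genes)
    k = len(experiments)
    t_vecs = [
        contrast_t(e, d, genes, extra_excluded=excluded) for e, d in experiments
    ]
    stats_m = np.zeros((k, k))
    p_m = np.ones((k, k))
    children = seed_seq.spawn(k * k)
    for i in range(k):
        for j in range(i, k):
            observed = v2(t_vecs[i], t_vecs[j])
            cell_rng = np.random.default_rng(children[i * k + j])
            e_i, d_i = experiments[i]
            e_j, d_j = experiments[j]
            d_i = PerturbationDesign(
                d_i.mutant_label, d_i.wt_label, d_i.compartment, frozenset(excluded)
            )
            d_j = PerturbationDesign(
                d_j.mutant_label, d_j.wt_label, d_j.compartment, frozenset(excluded)
            )
            if i == j:
                null = permutation_null(
                    e_i, e_i, d_i, d_i, genes, n_perm=n_perm, rng=cell_rng
                )
            else:
                null = permutation_null(
                    e_i, e_j, d_i, d_j, genes, n_perm=n_perm, rng=cell_rng
                )
            p = tail_p(null, observed, tail)
            stats_m[i, j] = stats_m[j, i] = observed
            p_m[i, j] = p_m[j, i] = p
    return V2Matrix(
        labels=labels,
        stats=pd.DataFrame(stats_m, index=labels, columns=labels),
        p_values=pd.DataFrame(p_m, index=labels, columns=labels),
    )


def fisher_tau(p_values) -> AggregateResult:
    """Aggregate independent p-values: τ = −2 Σ ln p, χ²(2n) upper tail."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p > 1.0) or np.any(p < 0.0):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0.0):
        warnings.warn("p = 0 clamped to smallest positive float", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    tau = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return AggregateResult(tau=tau, df=df, p_value=float(stats.chi2.sf(tau, df)))


def binomial_exceedance(p_values, alpha: float = 0.05) -> float:
    """P(X >= k), X ~ Binomial(n, alpha), with k = #{p < alpha}.

    More sensitive than Fisher's τ to sets where many p-values are moderate:
    a handful of tiny p-values cannot dominate the count. Returns 1 when no
    p-value clears alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    k = int(np.sum(p < alpha))
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, p.size, alpha))
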