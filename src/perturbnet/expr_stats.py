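"""Expression-matrix model and per-probe contrast statistics.

The toolkit consumes normalized (RMA-style, log-scale) probe-level intensity
matrices. Each gene may be represented by several probes; downstream
statistics either use all probes of a gene (the default for the
joint-perturbation statistic) or a single representative probe — the one with
maximum mean intensity — for correlation analyses and visualization.

The per-probe contrast statistic is the Welch (unequal-variance) t between a
mutant and a wild-type group within one tissue compartment. With equal group
sizes this equals the mean difference scaled by the pooled per-probe standard
deviation, sqrt(2*S_ii/n) with S_ii = (s²_mut + s²_wt)/2, which is the scaled
form the joint statistic multiplies across perturbations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph_core import _norm

__all__ = [
    "ExpressionMatrix",
    "PerturbationDesign",
    "TStatVector",
    "contrast_t",
    "max_intensity_probe",
    "spearman_matrix",
    "gene_correlation",
    "read_expression",
]

#: relative floor applied to pooled standard deviations (times the global
#: intensity SD) so degenerate constant probes cannot produce infinite t.
SD_FLOOR_FACTOR = 1e-8


class ExpressionMatrix:
    """Probe-level expression values with probe→gene map and sample annotations.

    Parameters
    ----------
    values
        DataFrame of log-scale intensities, probes in rows, samples in
        columns. All values must be finite.
    probe_to_gene
        Mapping from each probe id (row label) to exactly one gene symbol.
    sample_annotations
        DataFrame indexed by sample id with columns ``genotype``,
        ``compartment`` and ``replicate``.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        probe_to_gene: dict[str, str],
        sample_annotations: pd.DataFrame,
    ) -> None:
        values = values.astype(float)
        if not np.isfinite(values.to_numpy()).all():
            raise ValueError("expression values must all be finite")
        missing = set(values.index) - set(probe_to_gene)
        if missing:
            raise ValueError(f"probes without a gene assignment: {sorted(missing)[:5]}")
        required = {"genotype", "compartment", "replicate"}
        if not required <= set(sample_annotations.columns):
            raise ValueError(f"sample annotations need columns {sorted(required)}")
        if set(values.columns) != set(sample_annotations.index):
            raise ValueError("sample annotations must cover exactly the sample columns")
        self.values = values
        self.probe_to_gene = {str(p): _norm(g) for p, g in probe_to_gene.items()}
        self.sample_annotations = sample_annotations.loc[list(values.columns)]
        self._rep_probe_cache: dict[str, str] = {}
        self._gene_to_probes: dict[str, list[str]] = {}
        for probe in values.index:
            self._gene_to_probes.setdefault(self.probe_to_gene[str(probe)], []).append(
                str(probe)
            )

    # -- lookups ----------------------------------------------------------

    @property
    def genes(self) -> set[str]:
        return set(self._gene_to_probes)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def probes_for(self, gene: str) -> list[str]:
        gene = _norm(gene)
        if gene not in self._gene_to_probes:
            raise KeyError(f"gene {gene!r} has no probes")
        return sorted(self._gene_to_probes[gene])

    def has_gene(self, gene: str) -> bool:
        return _norm(gene) in self._gene_to_probes

    def samples_where(
        self, genotype: str | None = None, compartment: str | None = None
    ) -> list[str]:
        ann = self.sample_annotations
        mask = pd.Series(True, index=ann.index)
        if genotype is not None:
            mask &= ann["genotype"] == genotype
        if compartment is not None:
            mask &= ann["compartment"] == compartment
        return list(ann.index[mask])

    @property
    def compartments(self) -> list[str]:
        return sorted(self.sample_annotations["compartment"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.sample_annotations["genotype"].unique())


@dataclass
class PerturbationDesign:
    """One mutant-vs-wild-type contrast within a tissue compartment.

    ``excluded_genes`` must contain the mutated locus itself: its probes are
    dropped before any network statistic, because the engineered mutation
    gives them extreme intensities that would dominate the aggregate signal.
    """

    mutant_label: str
    wt_label: str
    compartment: str
    excluded_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.mutant_label == self.wt_label:
            raise ValueError("mutant and wild-type labels must differ")
        self.excluded_genes = frozenset(_norm(g) for g in self.excluded_genes)


@dataclass
class TStatVector:
    """Per-probe Welch t-statistics for one contrast, with components."""

    probes: list[str]
    t: np.ndarray
    mean_diff: np.ndarray
    pooled_sd: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.mean_diff = np.asarray(self.mean_diff, dtype=float)
        self.pooled_sd = np.asarray(self.pooled_sd, dtype=float)
        n = len(self.probes)
        if not (len(self.t) == len(self.mean_diff) == len(self.pooled_sd) == n):
            raise ValueError("component lengths disagree")
        if np.any(self.pooled_sd <= 0):
            raise ValueError("pooled_sd must be positive")


def _group_matrix(
    expr: ExpressionMatrix, genotype: str, compartment: str
) -> pd.DataFrame:
    cols = expr.samples_where(genotype=genotype, compartment=compartment)
    if len(cols) < 2:
        raise ValueError(
            f"group ({genotype!r}, {compartment!r}) has {len(cols)} replicate(s);"
            " need at least 2"
        )
    return expr.values[cols]


def welch_t(mut: np.ndarray, wt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t: (mean(mut) − mean(wt)) / sqrt(s²_mut/n_mut + s²_wt/n_wt).

    Returns (t, mean_diff, pooled_sd) where pooled_sd is the floored
    sqrt((s²_mut + s²_wt)/2) — the diagonal of the pooled covariance.
    """
    mut = np.atleast_2d(np.asarray(mut, dtype=float))
    wt = np.atleast_2d(np.asarray(wt, dtype=float))
    n_mut, n_wt = mut.shape[1], wt.shape[1]
    mean_diff = mut.mean(axis=1) - wt.mean(axis=1)
    var_mut = mut.var(axis=1, ddof=1)
    var_wt = wt.var(axis=1, ddof=1)
    global_sd = float(np.std(np.concatenate([mut.ravel(), wt.ravel()])))
    floor = SD_FLOOR_FACTOR * max(global_sd, 1.0)
    pooled_sd = np.maximum(np.sqrt((var_mut + var_wt) / 2.0), floor)
    se = np.sqrt(np.maximum(var_mut / n_mut + var_wt / n_wt, floor**2))
    return mean_diff / se, mean_diff, pooled_sd


def contrast_t(
    expr: ExpressionMatrix,
    design: PerturbationDesign,
    genes: Iterable[str],
    extra_excluded: Iterable[str] = (),
) -> TStatVector:
    """Welch t for every probe of ``genes`` in the design's contrast.

    Probes of ``design.excluded_genes`` (and of ``extra_excluded``, used to
    align probe lists across experiments) are dropped first.

    Probe order is deterministic: genes sorted, then probe ids sorted within
    each gene.
    """
    excluded = set(design.excluded_genes) | {_norm(g) for g in extra_excluded}
    kept = sorted({_norm(g) for g in genes} - excluded)
    probes: list[str] = []
    for gene in kept:
        if expr.has_gene(gene):
            probes.extend(expr.probes_for(gene))
    if not probes:
        raise ValueError("no probes remain after exclusions")
    mut = _group_matrix(expr, design.mutant_label, design.compartment).loc[probes]
    wt = _group_matrix(expr, design.wt_label, design.compartment).loc[probes]
    t, mean_diff, pooled_sd = welch_t(mut.to_numpy(), wt.to_numpy())
    return TStatVector(probes=probes, t=t, mean_diff=mean_diff, pooled_sd=pooled_sd)


def max_intensity_probe(expr: ExpressionMatrix, gene: str) -> str:
    """Representative probe: highest mean intensity across all samples.

    Exact ties resolve to the lexicographically first probe id. Cached per
    gene (the matrix is immutable by convention).
    """
    key = _norm(gene)
    cached = expr._rep_probe_cache.get(key)
    if cached is not None:
        return cached
    probes = expr.probes_for(gene)
    means = expr.values.loc[probes].mean(axis=1)
    best = means.max()
    winner = sorted(p for p in probes if means[p] == best)[0]
    expr._rep_probe_cache[key] = winner
    return winner


def gene_correlation(
    expr: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    method: str = "pearson",
    samples: Sequence[str] | None = None,
) -> float:
    """Correlation of the two genes' representative probes across samples.

    Constant probes (zero variance) yield an undefined correlation, recorded
    as 0 with a warning.
    """
    pa = max_intensity_probe(expr, gene_a)
    pb = max_intensity_probe(expr, gene_b)
    cols = list(samples) if samples is not None else list(expr.values.columns)
    xa = expr.values.loc[pa, cols].to_numpy(dtype=float)
    xb = expr.values.loc[pb, cols].to_numpy(dtype=float)
    if np.std(xa) == 0 or np.std(xb) == 0:
        warnings.warn(
            f"constant representative probe for {gene_a}/{gene_b};"
            " correlation recorded as 0",
            stacklevel=2,
        )
        return 0.0
    if method == "pearson":
        return float(stats.pearsonr(xa, xb).statistic)
    if method == "spearman":
        return float(stats.spearmanr(xa, xb).statistic)
    raise ValueError(f"unknown method {method!r}")


def spearman_matrix(
    expr: ExpressionMatrix,
    genes_a: Sequence[str],
    genes_b: Sequence[str],
) -> pd.DataFrame:
    """Spearman correlation matrix between representative probes.

    Computed across *all* samples (both genotypes, both compartments), per the
    coexpression analysis design. Constant probes give 0 entries, flagged via
    ``result.attrs["flagged"]``.
    """
    genes_a = [_norm(g) for g in genes_a]
    genes_b = [_norm(g) for g in genes_b]
    rows = {g: expr.values.loc[max_intensity_probe(expr, g)].to_numpy() for g in genes_a}
    cols = {g: expr.values.loc[max_intensity_probe(expr, g)].to_numpy() for g in genes_b}
    # rank once per gene; Spearman is Pearson on ranks
    rank_a = {g: stats.rankdata(v) for g, v in rows.items()}
    rank_b = {g: stats.rankdata(v) for g, v in cols.items()}
    out = np.zeros((len(genes_a), len(genes_b)))
    flagged: list[tuple[str, str]] = []
    mat_a = np.array([rank_a[g] for g in genes_a], dtype=float)
    mat_b = np.array([rank_b[g] for g in genes_b], dtype=float)
    sd_a = mat_a.std(axis=1)
    sd_b = mat_b.std(axis=1)
    ca = mat_a - mat_a.mean(axis=1, keepdims=True)
    cb = mat_b - mat_b.mean(axis=1, keepdims=True)
    n = mat_a.shape[1]
    cov = ca @ cb.T / n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = cov / np.outer(sd_a, sd_b)
    for i, ga in enumerate(genes_a):
        for j, gb in enumerate(genes_b):
            if sd_a[i] == 0 or sd_b[j] == 0:
                out[i, j] = 1.0 if ga == gb else 0.0
                flagged.append((ga, gb))
    result = pd.DataFrame(out, index=genes_a, columns=genes_b)
    if set(genes_a) == set(genes_b):
        for g in genes_a:
            if g in result.columns:
                result.loc[g, g] = 1.0
    result.attrs["flagged"] = flagged
    if flagged:
        warnings.warn(
            f"{len(flagged)} correlation(s) undefined (constant probe); set to 0",
            stacklevel=2,
        )
    return result


def read_expression(
    matrix_path: str | Path,
    probe_map_path: str | Path,
    annotations_path: str | Path,
) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from three TSV files.

    ``matrix_path``: probes × samples TSV with a header of sample ids and the
    probe id in the first column. ``probe_map_path``: 2-column TSV
    (probe, gene). ``annotations_path``: TSV with columns sample, genotype,
    compartment, replicate.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    probe_map_df = pd.read_csv(
        probe_map_path, sep="\t", header=None, names=["probe", "gene"]
    )
    probe_to_gene = dict(zip(probe_map_df["probe"].astype(str), probe_map_df["gene"]))
    ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    return ExpressionMatrix(values, probe_to_gene, ann)
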