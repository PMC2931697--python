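"""Two-phase interaction filtering: confidence pruning and family inference.

Interaction databases carry both false positives (spurious reported edges)
and false negatives (real interactions never assayed). Phase 1 prunes
low-confidence edges with a logistic regression over four evidence features:

(i)   how often the interaction was observed (log count),
(ii)  the Pearson coexpression of the two genes,
(iii) the mean small-world clustering coefficient of the two endpoints,
(iv)  whether the partners share a subcellular localization.

The model is trained on labelled positive/negative interaction sets over
repeated random holdout trials; the reported weights are the across-trial
mean, and per-trial held-out accuracy is kept as a training summary. Phase 2
recovers candidate false negatives: an unobserved pair (u, v) is inferred as
an edge when some protein family of u and some family of v contain an
observed interacting pair elsewhere in the network. Only observed edges serve
as evidence, so inference never chains on its own output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .expr_stats import ExpressionMatrix, gene_correlation
from .graph_core import (
    FAMILY_INFERRED,
    OBSERVED,
    EvidenceRecord,
    FamilyMap,
    Network,
    clustering_coefficient,
)

__all__ = [
    "FeatureVector",
    "ConfidenceModel",
    "featurize",
    "train_confidence",
    "score",
    "prune",
    "infer_family_edges",
]

FEATURE_NAMES = ("intercept", "obs_count", "coexpr", "clustering", "colocalized")

#: L2 ridge strength; small, only to guarantee convergence under separation.
RIDGE_LAMBDA = 1e-4


@dataclass
class FeatureVector:
    """Evidence features for one candidate interaction."""

    obs_count: float  # log of the observation count
    coexpr: float
    clustering: float
    colocalized: float
    coexpr_imputed: bool = False

    def __post_init__(self) -> None:
        for name in ("obs_count", "coexpr", "clustering", "colocalized"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"feature {name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.obs_count, self.coexpr, self.clustering, self.colocalized]
        )


@dataclass
class ConfidenceModel:
    """Fitted interaction-confidence model (results object).

    ``weights`` has length 5: intercept followed by the four feature weights
    in :data:`FEATURE_NAMES` order. ``training_summary`` is the held-out
    accuracy of each cross-validation trial.
    """

    weights: np.ndarray
    training_summary: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (5,):
            raise ValueError("weight vector must have length 5 (intercept + 4)")
        if any(not 0.0 <= a <= 1.0 for a in self.training_summary):
            raise ValueError("held-out accuracies must lie in [0, 1]")

    @property
    def mean_holdout_accuracy(self) -> float:
        if not self.training_summary:
            return float("nan")
        return float(np.mean(self.training_summary))

    def summary(self) -> str:
        lines = ["Interaction confidence model (logistic regression)"]
        for name, w in zip(FEATURE_NAMES, self.weights):
            lines.append(f"  {name:<12s} {w:+.4f}")
        lines.append(
            f"  trials: {len(self.training_summary)}; "
            f"mean held-out accuracy: {self.mean_holdout_accuracy:.3f}"
        )
        return "\n".join(lines)


def featurize(
    edge: tuple[str, str],
    net: Network,
    expr: ExpressionMatrix | None = None,
) -> FeatureVector:
    """Feature vector for an edge of ``net``.

    ``colocalized`` is 1 iff the endpoints' localization sets intersect;
    ``coexpr`` is the Pearson correlation of the genes' representative probes,
    imputed to 0 (and flagged) when either gene is missing from ``expr`` or
    no expression data is supplied.
    """
    u, v = edge
    if not net.has_edge(u, v):
        raise KeyError(f"edge ({u}, {v}) not in network")
    _, rec = net.edge_data(u, v)
    count = max(rec.observation_count, 1)
    coexpr, imputed = 0.0, True
    if rec.pearson_coexpression is not None:
        coexpr, imputed = float(rec.pearson_coexpression), False
    elif expr is not None and expr.has_gene(u) and expr.has_gene(v):
        coexpr, imputed = gene_correlation(expr, u, v, method="pearson"), False
    clustering = 0.5 * (
        clustering_coefficient(net, u) + clustering_coefficient(net, v)
    )
    coloc = float(bool(rec.localizations_u & rec.localizations_v))
    return FeatureVector(
        obs_count=math.log(count),
        coexpr=coexpr,
        clustering=clustering,
        colocalized=coloc,
        coexpr_imputed=imputed,
    )


def _design_matrix(features: list[FeatureVector]) -> np.ndarray:
    return np.array([fv.as_array() for fv in features])


def train_confidence(
    positives: list[FeatureVector],
    negatives: list[FeatureVector],
    n_trials: int = 1000,
    holdout: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> ConfidenceModel:
    """Fit the confidence model over repeated random holdout trials.

    Each trial draws an independent (1 − holdout)/holdout split of the pooled
    labelled examples, fits a maximum-likelihood logistic regression with a
    small L2 ridge (lambda = 1e-4, guarding against perfect separation), and
    records held-out accuracy. Final weights are the mean across trials.
    """
    if len(positives) < 10 or len(negatives) < 10:
        raise ValueError("need at least 10 positive and 10 negative examples")
    if not 0.0 < holdout < 1.0:
        raise ValueError("holdout fraction must lie in (0, 1)")
    rng = np.random.default_rng(rng)
    x = np.vstack([_design_matrix(positives), _design_matrix(negatives)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    n = len(y)
    n_test = max(1, int(round(holdout * n)))
    if np.any(x.std(axis=0) == 0):
        warnings.warn(
            "zero-variance feature in training data; ridge keeps it near 0",
            stacklevel=2,
        )
    weight_sum = np.zeros(5)
    accuracies: list[float] = []
    clf = LogisticRegression(C=1.0 / RIDGE_LAMBDA, solver="lbfgs", max_iter=1000)
    for _ in range(n_trials):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        # resplit if a class is missing from the training fold
        while len(np.unique(y[train_idx])) < 2:
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
        clf.fit(x[train_idx], y[train_idx])
        weight_sum += np.concatenate([clf.intercept_, clf.coef_.ravel()])
        accuracies.append(float(clf.score(x[test_idx], y[test_idx])))
    return ConfidenceModel(
        weights=weight_sum / n_trials, training_summary=accuracies
    )


def score(model: ConfidenceModel, fv: FeatureVector) -> float:
    """Predicted interaction probability: logistic(w·[1, features])."""
    eta = model.weights[0] + float(model.weights[1:] @ fv.as_array())
    # numerically safe logistic
    if eta >= 0:
        return 1.0 / (1.0 + math.exp(-eta))
    z = math.exp(eta)
    return z / (1.0 + z)


def prune(
    net: Network,
    model: ConfidenceModel,
    threshold: float = 0.5,
    expr: ExpressionMatrix | None = None,
) -> Network:
    """Phase 1: retain exactly the edges scoring at or above ``threshold``.

    Nodes are never removed, even if left isolated.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = Network()
    for node in net.node_list():
        out.add_node(node)
    for edge in net.edges():
        u, v = sorted(edge)
        fv = featurize((u, v), net, expr)
        if score(model, fv) >= threshold:
            origin, rec = net.edge_data(u, v)
            out.add_edge(
                u,
                v,
                origin=origin,
                evidence=EvidenceRecord(
                    observation_count=rec.observation_count,
                    pearson_coexpression=rec.pearson_coexpression,
                    localizations_u=rec.localizations_u,
                    localizations_v=rec.localizations_v,
                ),
            )
    return out


def infer_family_edges(net: Network, fam: FamilyMap) -> Network:
    """Phase 2: add family-inferred edges for unobserved pairs.

    A pair (u, v) gains an inferred edge iff it is not already an edge and
    some family of u and some family of v contain an observed interacting
    pair elsewhere in the network. Evidence comes from observed edges only,
    so applying the operation twice adds nothing (idempotence).
    """
    out = net.copy()
    interacting_families: set[frozenset[str]] = set()
    for edge in net.edges(origin=OBSERVED):
        u, v = tuple(edge)
        for fu in fam.families(u):
            for fv in fam.families(v):
                interacting_families.add(frozenset((fu, fv)))
    nodes = net.node_list()
    for i, u in enumerate(nodes):
        fams_u = fam.families(u)
        if not fams_u:
            continue
        for v in nodes[i + 1 :]:
            if net.has_edge(u, v):
                continue
            fams_v = fam.families(v)
            if any(
                frozenset((fu, fv)) in interacting_families
                for fu in fams_u
                for fv in fams_v
            ):
                out.add_edge(u, v, origin=FAMILY_INFERRED)
    return out
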