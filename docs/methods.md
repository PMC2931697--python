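# Methods

This note documents the statistical procedures implemented in `perturbnet`,
the parameters that matter, the numerical conventions, and what the
synthetic-data generators do and do not emulate.

## 1. Interaction filtering

### Confidence model

Each candidate interaction (u, v) is summarized by four features:

| feature | definition | range |
|---|---|---|
| `obs_count` | log of the number of independent reports of the edge | ≥ 0 |
| `coexpr` | Pearson correlation of the two genes' representative probes | [−1, 1] |
| `clustering` | mean of the endpoints' local clustering coefficients | [0, 1] |
| `colocalized` | 1 iff the endpoints' subcellular localization sets intersect | {0, 1} |

Counts enter on the log scale because report counts are heavy-tailed; a
missing coexpression value is imputed to 0 and flagged. The confidence
model is a maximum-likelihood logistic regression fit over repeated random
holdout trials (default 1000 trials, 80/20 split); the reported weights
are the across-trial mean and each trial's held-out accuracy is retained
as a training summary. A small L2 ridge (λ = 10⁻⁴) guarantees convergence
when the training classes are separable, which is likely on small labelled
sets; it also pins the weight of an uninformative (zero-variance) feature
near zero. Pruning keeps edges with predicted probability ≥ a threshold
(default 0.5, configurable — whether the original procedure thresholded
probability or odds, and where, is not documented, so the cutoff is
deliberately exposed). Nodes are never removed.

### Family-based edge inference

A pair (u, v) that is not an edge gains a `family-inferred` edge when some
family of u and some family of v contain an *observed* interacting pair
elsewhere in the network. Only observed edges serve as evidence: inferred
edges never beget further inferences, so the operation is idempotent and
cannot cascade transitively. Inferred edges carry observation count 0.

## 2. Path prediction

All simple source→sink paths with at most 6 nodes (endpoints included) are
enumerated, in deterministic lexicographic order. Two scores per path:

* **avg coexpression** — mean Pearson correlation of representative probes
  over consecutive gene pairs;
* **rule score** — for each consecutive pair, the maximum confidence over
  the pair's annotation-term combinations among rules mined from reference
  pathways, averaged along the path. A rule (g₁, g₂) has support equal to
  the number of pathway edges whose endpoints carry those terms (both
  orientations counted, pathway edges being undirected) and confidence
  equal to support divided by the number of pathway proteins annotated
  with the antecedent term.

A path survives iff its coexpression clears a user threshold (default
0.5 — this threshold is data-dependent in any real application and must be
chosen by the user) **and** its rule score exceeds the (1 − α) quantile
(α = 0.01) of rule scores over 1000 random simple paths of the same
length, drawn by random walk without node revisits. The matched-length
random-path null is this package's operationalization of "path
significance"; nothing finer-grained is documented for the original
procedure. The union of surviving paths' edges, with their
observed/inferred origin labels, is the predicted subnetwork. Raising
either threshold can only shrink the output.

## 3. Per-probe contrasts

Expression input is a normalized (RMA-style, log-scale) probe × sample
matrix with a probe→gene map and per-sample genotype/compartment/replicate
annotations; missing values are not supported. The per-probe statistic for
one mutant-vs-wild-type contrast within one compartment is the Welch
(unequal-variance) t. With equal group sizes n this equals
Δμ / sqrt(2·S_ii/n) where S_ii = (s²_mut + s²_wt)/2 is the diagonal of the
pooled covariance — the "scaled t" form whose product the joint statistic
sums. The exact display of the pooled-covariance scaling in the source
material is unavailable, so this equal-n Welch interpretation is adopted
and isolated inside `contrast_t` so it can be swapped. Pooled SDs are
floored at 10⁻⁸ × the global intensity SD to keep degenerate constant
probes finite.

A gene's **representative probe** (used for all correlation analyses and
for visualization-style statistics) is the probe with the highest mean
intensity across all samples; exact ties resolve to the lexicographically
first probe id. Spearman correlations are computed across *all* samples —
both genotypes, both compartments — matching the design in which
coexpression spans the whole perturbation panel.

## 4. The V² joint-perturbation test

For two experiments A and B sharing a probe list (network genes minus the
pooled excluded genes — always including each experiment's mutated locus,
whose engineered expression would dominate the aggregate):

    V² = Σᵢ tᵢ⁽ᴬ⁾ tᵢ⁽ᴮ⁾.

Off-diagonal covariances are zeroed (q ≫ n makes sample covariance
matrices singular); the lost covariance structure is preserved instead in
the permutation null. V² is signed; the self-pair A = B gives Σ t², a
scaled diagonal-covariance Hotelling T² (the algebraic identity
Σt² = (n/2)·Σ Δμ²/S_ii is verified in the test suite). Genes with many
probes contribute proportionally more, by design.

**Permutation null.** Per permutation, phenotype labels are reshuffled
within each experiment independently, preserving group sizes; the two
experiments are relabeled independently because they are modeled as
independent perturbations (each with its own wild-type replicate group —
see §7). Because groups are small (n = 4), the discrete permutation space
is coarse; per-entry Gaussian noise with SD equal to the probe's sample SD
within its original genotype group is added to each permuted matrix,
interpolating and smoothing the null. The t statistic is
scale-self-normalizing, so this smoothing widens nothing systematically
(type-I calibration is verified empirically). Noise is added only to
permuted data, never to the observed statistic. Default 10 000
permutations.

**Tails.** p = (1 + #{null ≥ V²obs}) / (n_perm + 1) for the positive tail
(expected when both perturbations should act in the same direction, e.g.
two tumor suppressors); the negative tail mirrors it (antagonistic pairs).
The add-one correction keeps p strictly positive — the raw count estimator
can return an exact zero, which would break downstream log-aggregation.

**k experiments.** All pairwise statistics form a k×k matrix; each entry
gets its own permutation null (the statistics live on different scales and
cannot be compared directly), with RNG substreams split per cell so the
matrix is reproducible regardless of evaluation order. Diagonal entries
carry within-experiment significance; off-diagonal entries carry joint
support and can be aggregated by Fisher's method for k > 2.

## 5. Target-set association

**2-hop proximity.** D2(i, k) = 1 iff an intermediate j ∉ {i, k} exists
with A[i][j] = A[j][k] = 1. With a hollow symmetric adjacency matrix the
exclusion of j ∈ {i, k} is automatic, so the implementation is the boolean
of (A²)[i, ·] > 0 with the diagonal cleared; requiring j to differ from
both endpoints is the only biologically meaningful reading. Connectivity
Cᵢ counts targets 2-hop reachable from i; the query node is removed from
the target set if present. The empirical null redraws size-n sets
uniformly from all network nodes except the query node (default 10 000
draws); p is the add-one-smoothed upper tail. Because Cᵢ is
integer-valued, its p-values are conservative when the null distribution
is concentrated; calibration checks therefore use regimes where 2-hop
reach is far from saturated (see §8).

**Weighted Kuiper coexpression test.** Let r be the descending-ordered
vector of Spearman correlations between one node's representative probe
and every gene in the universe (the node itself excluded). The member
(target) CDF steps |r|^w at member positions, normalized to sum 1
(w = 1 by default, the GSEA-recommended weighting; w = 0 recovers the
classic two-sample Kuiper statistic, verified to 10⁻¹² against a direct
ECDF scan); the control CDF steps uniformly at non-members. K = D⁺ + D⁻,
the sum of maximal positive and negative deviations — sensitive to the
bimodal shifts coregulated sets produce, since coexpressed partners show
both positive and negative correlations. If all member correlations are
exactly zero the weights fall back to uniform with a warning. The null is
K over 500 random same-size sets with a maximum-likelihood normal fit
(μ̂, σ̂ with the 1/n variance); p is the fitted upper tail (one-sided:
larger K = stronger deviation). Leading-edge subsets: members at or before
the position of the maximal positive deviation (`leading_pos`), members
after the position of the maximal negative deviation (`leading_neg`);
a member qualifying for both — possible only when the two extreme
positions bracket it — is assigned to the larger-deviation side, so
singleton sets land in exactly one subset. The exact leading-edge
cutoff formulas in the source material are unavailable; this
GSEA-analogous gap-position rule is adopted and isolated.

**Differentially expressed nodes.** A gene qualifies when the
unequal-variance t of its maximum-intensity probe exceeds Φ⁻¹(1 − α/2) in
magnitude in at least one supplied contrast (per mutant, per compartment;
α = 0.05). The normal rather than t quantile follows the original
selection rule; at n = 4 it is mildly anti-conservative, which is
acceptable for a screening step.

**Aggregation.** Fisher's τ = −2 Σ ln pᵢ against χ² with 2n degrees of
freedom (exact identity p_out = p_in at n = 1); zero p-values are clamped
to the smallest positive float with a warning. The binomial exceedance
P(X ≥ #{p < α}), X ~ Binomial(n, α), complements τ: it is driven by the
count of small p-values rather than their product, hence more sensitive
to sets where many p-values are moderate. The mutated gene is excluded
from its own experiment's aggregation.

## 6. Synthetic-study generators

The generators produce data with the structure the analyses assume — not
realistic microarray artifacts (no batch effects, saturation, or
sequence-level detail).

* **Network**: preferential attachment (degree-heterogeneous, like real
  interactomes; default 150 nodes, attachment 2) or Erdős–Rényi when a
  homogeneous control topology is needed. Edge observation counts
  1 + Poisson(1).
* **Families**: a uniform random partition into 30 families.
* **Expression**: two mutant genotypes and two compartments with 4
  replicates per cell, matching the standard single-node-perturbation
  design. Gene baselines ~ N(8, 1) on the log scale (RMA output is
  approximately Gaussian there), per-probe offsets ~ N(0, 0.5), residual
  noise SD 0.25, and 1–7 probes per gene (real arrays probe well-studied
  genes multiply). Planted effects shift each network gene by
  `effect_size` noise-SD units in the crypt compartment, with a per-gene
  random direction that is shared across mutants (`shared`, the V²
  alternative), opposed (`opposite`), or absent (`none`); probes of one
  gene share the gene effect but have independent noise. The truth record
  stores every planted direction, sufficient to score recovery without
  re-simulation.
* **Wild-type groups**: each mutant is paired with its *own* wild-type
  replicate group (`WTA`/`WTB`). A shared control pool would correlate
  the two experiments' t-vectors (≈ 0.5 under the null) and would require
  a joint relabeling scheme; with independent controls the experiments
  are exchangeable under the independent within-experiment relabeling
  the permutation test uses, and Fisher aggregation's independence
  assumption holds.
* **Targets**: sampled from the union of the network genes' 2-hop
  neighbourhoods, excluding the network genes themselves — the situation
  a downstream proteomic screen produces.
* **Corridor cases** (for path-prediction recovery): a planted
  source→sink chain whose genes share a latent expression factor
  (pairwise correlation ≈ 0.8) and whose consecutive annotation pairs are
  supported by a generated reference pathway, embedded in a 200-node
  preferential-attachment background with decoy annotations. The
  background is deliberately sized so the planted chain occupies well
  under 1% of the matched-length random-path null: in a very small graph
  the random-walk path sampler funnels through low-degree chains and the
  corridor would contaminate its own null — a small-scale artifact absent
  at realistic network sizes.

All generators are pure functions of their spec (the seed is a mandatory
spec field).

## 7. What passing tests show — and do not show

Calibration and power results on these generators demonstrate that the
statistics behave as designed under their own assumptions: Gaussian
log-intensities, independent experiments, exchangeable replicates,
planted effects aligned with the alternative. They do not demonstrate
robustness to batch structure, outlier arrays, correlated background
genes, or mis-specified probe→gene maps, none of which the generators
emulate.

## 8. Numerical and scenario choices

* Add-one smoothing for all empirical-null p-values (never exactly 0 or
  below 1/(draws+1)).
* RNG: a single seed governs each routine; multi-cell computations split
  substreams via `SeedSequence.spawn` per cell.
* Type-I calibration of the V² pipeline uses 500 effect-free repeats at
  200 permutations each (group size 4, 12 genes), compared against the
  exact binomial 95% interval at α = 0.05. The reduced permutation count
  keeps the check fast; the add-one estimator's attainable p-values make
  the effective level 10/201 ≈ 0.0497, well inside the interval's
  resolution.
* Proximity-p calibration uses an Erdős–Rényi graph (2000 nodes, edge
  probability 0.017, ≈ 50% two-hop reach) with 800-gene target sets:
  chosen analytically so the integer statistic's null has small point
  masses (SD ≈ 11, max mass ≈ 0.04) and the discreteness-induced
  conservatism stays far below the KS rejection threshold. Kuiper-p
  calibration varies the tested node across repeats so no single gene's
  fixed correlation profile dominates, and uses the method's default 500
  null sets.
* Power checks (shared-direction plants at 1.5 SD) and corridor recovery
  (20 seeds) run at the generator defaults above; problem sizes
  throughout (12–20 genes, 200–2000 permutations/draws per check) are the
  package's own test-design choices balancing Monte-Carlo resolution
  against suite runtime.

## 9. Known limitations

* The coexpression path threshold has no principled default; 0.5 is a
  placeholder the user must calibrate per dataset.
* The random-walk null path sampler is not uniform over simple paths; it
  over-represents paths through low-degree nodes. Documented, and
  irrelevant at realistic network sizes.
* The normal approximation to the Kuiper null is an approximation; for
  very small target sets or universes the fitted tail can deviate.
* Proximity p-values are conservative in saturated-reachability regimes
  (dense graphs, hub queries): if nearly every node is 2-hop reachable,
  the test has no power by construction.
* Directionality of signaling, probabilistic localization evidence, and
  cross-database identifier mapping are out of scope; inputs are consumed
  pre-mapped.
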