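"""Synthetic study generators: networks, families, expression, target sets.

Every analysis in this toolkit is exercised against generated data whose
statistical structure matches what the methods assume:

* a degree-heterogeneous interaction network (preferential attachment, or an
  Erdős–Rényi graph when a homogeneous control topology is wanted);
* a random protein-family partition;
* probe-level log-scale expression for a two-perturbation, two-compartment
  design — two mutant genotypes, each with its own wild-type replicate
  group, four replicates per (genotype, compartment) cell by default — with
  genes represented by 1–7 probes and planted network-gene effects whose
  direction is shared across mutants, opposed, or absent;
* proteomic target sets planted inside the 2-hop neighbourhood of the
  network genes.

Each mutant is paired with an independent wild-type replicate group so the
two contrasts are statistically independent, matching the independence
assumed by the joint statistic's permutation scheme.

Generators are pure functions of their spec (the seed is part of the spec),
and each returns a truth record sufficient to score recovery without
re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .expr_stats import ExpressionMatrix, PerturbationDesign
from .graph_core import FamilyMap, GeneSet, Network, adjacency
from .target_assoc import two_hop_reachable

__all__ = [
    "ScenarioSpec",
    "SyntheticCase",
    "make_ppi",
    "make_families",
    "make_expression",
    "plant_targets",
    "make_case",
    "make_corridor_case",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic study; the seed is mandatory.

    ``effect_size`` is the planted mean shift in units of the within-group
    noise SD; ``effect_sign_mode`` is ``shared`` (both mutants move each
    network gene the same way — the joint-statistic alternative),
    ``opposite``, or ``none`` (pure null). Effects are planted in
    ``effect_compartments`` only, mirroring compartment-specific biology.
    """

    seed: int
    n_nodes: int = 150
    attachment: int = 2
    topology: str = "scale-free"  # or "er"
    er_edge_prob: float = 0.03
    n_families: int = 30
    universe_size: int = 120
    n_network_genes: int = 20
    max_probes_per_gene: int = 7
    replicates: int = 4
    compartments: tuple[str, ...] = ("crypt", "villus")
    mutant_labels: tuple[str, str] = ("MUTA", "MUTB")
    wt_labels: tuple[str, str] = ("WTA", "WTB")
    effect_size: float = 1.5
    effect_sign_mode: str = "shared"
    effect_compartments: tuple[str, ...] = ("crypt",)
    n_targets: int = 30
    target_radius: int = 2
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    probe_offset_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.effect_sign_mode not in ("shared", "opposite", "none"):
            raise ValueError("effect_sign_mode must be shared/opposite/none")
        for count in (
            self.n_nodes,
            self.n_families,
            self.universe_size,
            self.n_network_genes,
            self.replicates,
            self.max_probes_per_gene,
        ):
            if count < 1:
                raise ValueError("all counts must be positive")
        if self.topology not in ("scale-free", "er"):
            raise ValueError("topology must be 'scale-free' or 'er'")


@dataclass
class SyntheticCase:
    """A mutually consistent bundle for end-to-end tests."""

    spec: ScenarioSpec
    network: Network
    families: FamilyMap
    expression: ExpressionMatrix
    designs: list[PerturbationDesign]
    network_genes: list[str]
    targets: GeneSet
    truth: dict


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def make_ppi(spec: ScenarioSpec) -> Network:
    """Random interaction network, deterministic per seed.

    ``scale-free`` uses preferential attachment (degree-heterogeneous, like
    real interactomes); ``er`` gives a homogeneous Erdős–Rényi control.
    Observation counts are drawn 1 + Poisson(1) to exercise the evidence
    model.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.topology == "scale-free":
        if spec.n_nodes == 1:
            g = nx.empty_graph(1)
        else:
            m = spec.attachment
            if m >= spec.n_nodes:
                raise ValueError(
                    "attachment parameter must be below the node count"
                )
            g = nx.barabasi_albert_graph(
                spec.n_nodes, m, seed=int(rng.integers(2**31))
            )
    else:
        g = nx.gnp_random_graph(
            spec.n_nodes, spec.er_edge_prob, seed=int(rng.integers(2**31))
        )
    net = Network()
    for i in range(spec.n_nodes):
        net.add_node(_node_name(i))
    for u, v in sorted(g.edges()):
        count = 1 + int(rng.poisson(1.0))
        net.add_edge(_node_name(u), _node_name(v))
        _, rec = net.edge_data(_node_name(u), _node_name(v))
        rec.observation_count = count
    return net


def make_families(net: Network, spec: ScenarioSpec) -> FamilyMap:
    """Random partition of the nodes into ``n_families`` families."""
    rng = np.random.default_rng(spec.seed + 1)
    nodes = net.node_list()
    if spec.n_families > len(nodes):
        raise ValueError("cannot have more families than nodes")
    order = rng.permutation(len(nodes))
    assignment = {
        nodes[idx]: frozenset({f"FAM{idx_round % spec.n_families:03d}"})
        for idx_round, idx in enumerate(order)
    }
    return FamilyMap(assignment=assignment)


def make_expression(
    spec: ScenarioSpec, network_genes: list[str]
) -> tuple[ExpressionMatrix, dict]:
    """Probe-level expression with planted network-gene effects.

    Baseline log-intensities are Gaussian per gene with per-probe offsets;
    probes of one gene share the gene's effect but carry independent noise.
    The truth record stores each network gene's planted shift direction per
    mutant.
    """
    rng = np.random.default_rng(spec.seed + 2)
    network_genes = [g.upper() for g in network_genes]
    n_extra = spec.universe_size - len(network_genes)
    if n_extra < 0:
        raise ValueError("universe_size smaller than the network gene list")
    background = [f"BG{i:04d}" for i in range(n_extra)]
    universe = network_genes + background

    genotypes = list(spec.mutant_labels) + list(spec.wt_labels)
    samples, records = [], []
    for genotype in genotypes:
        for comp in spec.compartments:
            for rep in range(1, spec.replicates + 1):
                sid = f"{genotype}_{comp}_r{rep}"
                samples.append(sid)
                records.append((sid, genotype, comp, rep))
    ann = pd.DataFrame(
        records, columns=["sample", "genotype", "compartment", "replicate"]
    ).set_index("sample")

    signs = {}
    for gene in network_genes:
        signs[gene] = int(rng.choice([-1, 1]))
    shift = {label: {} for label in spec.mutant_labels}
    if spec.effect_sign_mode != "none":
        for gene in network_genes:
            s = signs[gene]
            shift[spec.mutant_labels[0]][gene] = s
            shift[spec.mutant_labels[1]][gene] = (
                s if spec.effect_sign_mode == "shared" else -s
            )

    probe_rows, probe_ids, probe_to_gene = [], [], {}
    effect = spec.effect_size * spec.noise_sd
    for gene in universe:
        k = int(rng.integers(1, spec.max_probes_per_gene + 1))
        baseline = rng.normal(spec.baseline_mean, spec.baseline_sd)
        offsets = rng.normal(0.0, spec.probe_offset_sd, size=k)
        for j in range(k):
            pid = f"{gene}_p{j + 1}"
            probe_ids.append(pid)
            probe_to_gene[pid] = gene
            row = np.empty(len(samples))
            for s_idx, (sid, genotype, comp, _rep) in enumerate(records):
                mu = baseline + offsets[j]
                if (
                    genotype in shift
                    and gene in shift[genotype]
                    and comp in spec.effect_compartments
                ):
                    mu += shift[genotype][gene] * effect
                row[s_idx] = mu + rng.normal(0.0, spec.noise_sd)
            probe_rows.append(row)
    values = pd.DataFrame(np.array(probe_rows), index=probe_ids, columns=samples)
    expr = ExpressionMatrix(values, probe_to_gene, ann)
    truth = {
        "mode": spec.effect_sign_mode,
        "effect_size": spec.effect_size,
        "effect_compartments": list(spec.effect_compartments),
        "signs": signs,
        "shift": {m: dict(d) for m, d in shift.items()},
        "network_genes": list(network_genes),
        "background_genes": background,
    }
    return expr, truth


def plant_targets(
    net: Network,
    network_genes: list[str],
    n_targets: int,
    rng: np.random.Generator | int | None = None,
    name: str = "planted_targets",
) -> GeneSet:
    """Target set sampled from the union of the genes' 2-hop neighbourhoods.

    Network genes themselves are excluded from the candidate pool, so every
    target is a distinct protein 2-hop reachable from at least one network
    gene (the situation produced by a proteomic screen downstream of the
    network).
    """
    rng = np.random.default_rng(rng)
    ordering = net.node_list()
    a = adjacency(net, ordering)
    index = {node: i for i, node in enumerate(ordering)}
    pool_mask = np.zeros(len(ordering), dtype=bool)
    genes = [g.upper() for g in network_genes]
    for gene in genes:
        if gene not in index:
            raise KeyError(f"network gene {gene!r} not in graph")
        pool_mask |= two_hop_reachable(a, index[gene])
    for gene in genes:
        pool_mask[index[gene]] = False
    pool = [ordering[i] for i in np.flatnonzero(pool_mask)]
    if len(pool) < n_targets:
        raise ValueError(
            f"2-hop pool has only {len(pool)} candidates; {n_targets} requested"
        )
    chosen = rng.choice(len(pool), size=n_targets, replace=False)
    return GeneSet(name=name, members=frozenset(pool[i] for i in sorted(chosen)))


def make_case(spec: ScenarioSpec) -> SyntheticCase:
    """Generate a full, mutually consistent synthetic study."""
    net = make_ppi(spec)
    families = make_families(net, spec)
    rng = np.random.default_rng(spec.seed + 3)
    nodes = net.node_list()
    if spec.n_network_genes > len(nodes):
        raise ValueError("n_network_genes exceeds the node count")
    # prefer a connected, well-embedded gene group: take a breadth-first ball
    g = net.graph
    start = nodes[int(rng.integers(len(nodes)))]
    order = [start] + [v for _, v in nx.bfs_edges(g, start)]
    network_genes = sorted(order[: spec.n_network_genes])
    expr, truth = make_expression(spec, network_genes)
    targets = plant_targets(
        net, network_genes, spec.n_targets, rng=np.random.default_rng(spec.seed + 4)
    )
    designs = [
        PerturbationDesign(
            mutant_label=spec.mutant_labels[i],
            wt_label=spec.wt_labels[i],
            compartment=comp,
            excluded_genes=frozenset({network_genes[0]}),
        )
        for i in range(2)
        for comp in spec.compartments
    ]
    truth = dict(truth, targets=sorted(targets.members))
    return SyntheticCase(
        spec=spec,
        network=net,
        families=families,
        expression=expr,
        designs=designs,
        network_genes=network_genes,
        targets=targets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# planted corridor for path-prediction recovery
# ---------------------------------------------------------------------------


def make_corridor_case(
    seed: int,
    n_background: int = 200,
    attachment: int = 2,
    corridor_length: int = 4,
    n_samples: int = 30,
    corridor_noise: float = 0.5,
    n_decoy_terms: int = 20,
) -> dict:
    """A planted source→sink corridor in a random background network.

    The corridor is a chain of ``corridor_length`` genes (source and sink
    included) whose expression shares a latent factor (high pairwise
    coexpression) and whose consecutive annotation-term pairs are supported
    by a generated reference pathway, so the mined rules give the corridor
    confidence-1 support. Background genes get independent expression and
    decoy annotations. Returns a dict with the network, expression,
    annotations, mined-rule inputs and the true corridor edges.
    """
    if corridor_length < 3:
        raise ValueError("corridor needs at least 3 nodes")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(
        n_background, attachment, seed=int(rng.integers(2**31))
    )
    # source/sink are late-attachment (low-degree) background nodes
    bg_names = [f"BG{i:03d}" for i in range(n_background)]
    net = Network()
    for name in bg_names:
        net.add_node(name)
    for u, v in sorted(g.edges()):
        net.add_edge(bg_names[u], bg_names[v])
    source, sink = bg_names[-1], bg_names[-2]
    corridor = [source] + [
        f"CR{i:02d}" for i in range(1, corridor_length - 1)
    ] + [sink]
    corridor_edges = []
    for a, b in zip(corridor[:-1], corridor[1:]):
        net.add_edge(a, b)
        corridor_edges.append(frozenset((a, b)))

    # expression: corridor genes share a latent factor
    all_genes = sorted(net.nodes)
    latent = rng.normal(size=n_samples)
    rows, probe_to_gene = [], {}
    for gene in all_genes:
        if gene in corridor:
            x = latent + corridor_noise * rng.normal(size=n_samples)
        else:
            x = rng.normal(size=n_samples)
        pid = f"{gene}_p1"
        probe_to_gene[pid] = gene
        rows.append((pid, 8.0 + x))
    samples = [f"WT_crypt_r{i + 1}" for i in range(n_samples)]
    values = pd.DataFrame(
        np.array([r for _, r in rows]), index=[p for p, _ in rows], columns=samples
    )
    ann = pd.DataFrame(
        {
            "genotype": ["WT"] * n_samples,
            "compartment": ["crypt"] * n_samples,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=samples,
    )
    expr = ExpressionMatrix(values, probe_to_gene, ann)

    # GO annotations: a term chain along the corridor, decoys elsewhere
    chain_terms = [f"GO:C{i:03d}" for i in range(corridor_length)]
    annotations: dict[str, frozenset[str]] = {
        gene: frozenset({chain_terms[i]}) for i, gene in enumerate(corridor)
    }
    decoys = [f"GO:D{i:03d}" for i in range(n_decoy_terms)]
    for gene in all_genes:
        if gene not in annotations:
            annotations[gene] = frozenset({decoys[int(rng.integers(n_decoy_terms))]})
    # reference pathway whose edges carry the corridor's term chain
    pathway_nodes = [f"PW{i:02d}" for i in range(corridor_length)]
    pathway_edges = list(zip(pathway_nodes[:-1], pathway_nodes[1:]))
    for i, node in enumerate(pathway_nodes):
        annotations[node] = frozenset({chain_terms[i]})

    return {
        "network": net,
        "expression": expr,
        "annotations": annotations,
        "pathway_edges": pathway_edges,
        "source": source,
        "sink": sink,
        "corridor_nodes": corridor,
        "corridor_edges": corridor_edges,
    }
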