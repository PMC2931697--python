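"""Graph data model and readers shared by the whole toolkit.

The central object is :class:`Network`, an undirected graph of gene/protein
nodes whose edges carry provenance (experimentally observed vs. inferred from
protein-family relationships) and an :class:`EvidenceRecord` with the raw
evidence the confidence model consumes: how often the interaction was
reported, the coexpression of the two genes, and the subcellular compartments
each partner has been localized to.

Gene symbols are normalized to uppercase at ingest, because interaction and
annotation sources mix species casing conventions (``Apc`` vs ``APC``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "EvidenceRecord",
    "Network",
    "FamilyMap",
    "GeneSet",
    "ParseError",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_label_map",
    "adjacency",
    "clustering_coefficient",
]

OBSERVED = "observed"
FAMILY_INFERRED = "family-inferred"


class ParseError(ValueError):
    """A malformed row in an input file; the message names the line number."""


@dataclass
class EvidenceRecord:
    """Per-edge evidence consumed by the interaction confidence model.

    ``observation_count`` is the number of independent reports of the
    interaction (>= 1 for observed edges, 0 allowed for inferred ones);
    ``pearson_coexpression`` is the expression correlation of the two genes,
    if known; the localization sets hold subcellular compartment labels for
    each endpoint.
    """

    observation_count: int = 1
    pearson_coexpression: float | None = None
    localizations_u: frozenset[str] = frozenset()
    localizations_v: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.observation_count < 0:
            raise ValueError("observation_count must be nonnegative")
        if self.pearson_coexpression is not None and not (
            -1.0 <= self.pearson_coexpression <= 1.0
        ):
            raise ValueError("pearson_coexpression must lie in [-1, 1]")


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


class Network:
    """Undirected gene/protein interaction network.

    Thin wrapper over a :class:`networkx.Graph` that enforces the toolkit's
    invariants: symbols uppercased, no self-loops, every edge carrying an
    ``origin`` label and an :class:`EvidenceRecord`. Duplicate edge insertions
    aggregate into ``observation_count`` instead of parallel edges.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node: str) -> str:
        node = _norm(node)
        self._g.add_node(node)
        return node

    def add_edge(
        self,
        u: str,
        v: str,
        origin: str = OBSERVED,
        evidence: EvidenceRecord | None = None,
    ) -> None:
        u, v = _norm(u), _norm(v)
        if u == v:
            warnings.warn(f"dropping self-loop on {u}", stacklevel=2)
            self._g.add_node(u)
            return
        if origin not in (OBSERVED, FAMILY_INFERRED):
            raise ValueError(f"unknown edge origin {origin!r}")
        if self._g.has_edge(u, v):
            rec: EvidenceRecord = self._g.edges[u, v]["evidence"]
            incr = evidence.observation_count if evidence is not None else 1
            rec.observation_count += incr
            # an observed report upgrades an inferred edge
            if origin == OBSERVED:
                self._g.edges[u, v]["origin"] = OBSERVED
            return
        if evidence is None:
            count = 1 if origin == OBSERVED else 0
            evidence = EvidenceRecord(observation_count=count)
        if origin == OBSERVED and evidence.observation_count < 1:
            raise ValueError("observed edges require observation_count >= 1")
        self._g.add_edge(u, v, origin=origin, evidence=evidence)

    def copy(self) -> "Network":
        out = Network()
        out._g = self._g.copy()
        for u, v in out._g.edges():
            out._g.edges[u, v]["evidence"] = _copy_record(
                out._g.edges[u, v]["evidence"]
            )
        return out

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes())

    def node_list(self) -> list[str]:
        """Nodes in sorted order (the canonical ordering for matrices)."""
        return sorted(self._g.nodes())

    def edges(self, origin: str | None = None) -> set[frozenset[str]]:
        out = set()
        for u, v, data in self._g.edges(data=True):
            if origin is None or data["origin"] == origin:
                out.add(frozenset((u, v)))
        return out

    def has_node(self, node: str) -> bool:
        return _norm(node) in self._g

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(_norm(u), _norm(v))

    def edge_data(self, u: str, v: str) -> tuple[str, EvidenceRecord]:
        d = self._g.edges[_norm(u), _norm(v)]
        return d["origin"], d["evidence"]

    def neighbors(self, node: str) -> set[str]:
        return set(self._g.neighbors(_norm(node)))

    def degree(self, node: str) -> int:
        return int(self._g.degree(_norm(node)))

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def to_networkx(self) -> nx.Graph:
        """A defensive copy as a plain networkx graph."""
        return self._g.copy()

    @property
    def graph(self) -> nx.Graph:
        """Read-only view of the backing graph (do not mutate)."""
        return self._g

    def __contains__(self, node: str) -> bool:
        return self.has_node(node)

    def __iter__(self) -> Iterator[str]:
        return iter(self._g.nodes())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Network {self.number_of_nodes()} nodes,"
            f" {self.number_of_edges()} edges>"
        )


def _copy_record(rec: EvidenceRecord) -> EvidenceRecord:
    return EvidenceRecord(
        observation_count=rec.observation_count,
        pearson_coexpression=rec.pearson_coexpression,
        localizations_u=rec.localizations_u,
        localizations_v=rec.localizations_v,
    )


@dataclass
class FamilyMap:
    """Node -> set of protein-family identifiers (e.g. Pfam accessions).

    Nodes absent from ``assignment`` are treated as unassigned.
    """

    assignment: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, frozenset[str]] = {}
        for node, fams in self.assignment.items():
            fams = frozenset(str(f) for f in fams)
            if any(not f for f in fams):
                raise ValueError("family identifiers must be non-empty")
            cleaned[_norm(node)] = fams
        self.assignment = cleaned

    def families(self, node: str) -> frozenset[str]:
        return self.assignment.get(_norm(node), frozenset())


@dataclass
class GeneSet:
    """A named set of gene symbols (target lists, null draws, pathways)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(_norm(m) for m in self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, dialect: str = "tsv") -> Network:
    """Read an interaction network from a TSV edge list or a SIF file.

    TSV rows are ``nodeA<tab>nodeB[<tab>count]``; SIF rows are
    ``nodeA relation nodeB [nodeC ...]`` (whitespace separated, one edge per
    trailing node). Duplicate rows aggregate into ``observation_count``;
    self-loop rows are dropped with a warning.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = Network()
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if dialect == "tsv" else line.split()
            if dialect == "tsv":
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise ParseError(f"{path.name}:{lineno}: expected two node columns")
                u, v = fields[0], fields[1]
                count = 1
                if len(fields) >= 3 and fields[2].strip():
                    try:
                        count = int(fields[2])
                    except ValueError as exc:
                        raise ParseError(
                            f"{path.name}:{lineno}: bad count {fields[2]!r}"
                        ) from exc
                net.add_edge(u, v, evidence=EvidenceRecord(observation_count=count))
            else:
                if len(fields) == 1:
                    net.add_node(fields[0])
                    continue
                if len(fields) < 3:
                    raise ParseError(
                        f"{path.name}:{lineno}: SIF rows need source, relation,"
                        " and at least one target"
                    )
                u = fields[0]
                for v in fields[2:]:
                    net.add_edge(u, v)
    return net


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write a TSV edge list (nodeA, nodeB, count, origin); sorted rows."""
    rows = []
    for edge in net.edges():
        u, v = sorted(edge)
        origin, rec = net.edge_data(u, v)
        rows.append((u, v, rec.observation_count, origin))
    with Path(path).open("w") as fh:
        for u, v, count, origin in sorted(rows):
            fh.write(f"{u}\t{v}\t{count}\t{origin}\n")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, GeneSet] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: GMT rows need name, description,"
                    " and at least one member"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path.name}:{lineno}: duplicate set {name!r}")
            members = frozenset(m for m in fields[2:] if m.strip())
            if not members:
                raise ParseError(f"{path.name}:{lineno}: set {name!r} is empty")
            sets[name] = GeneSet(name=name, members=members)
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gs in sets:
            fh.write(gs.name + "\tna\t" + "\t".join(sorted(gs.members)) + "\n")


def read_label_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a 2-column TSV (node, label); repeated rows collect multi-labels.

    Used for protein-family maps, subcellular localization tables and GO
    annotation tables alike.
    """
    out: dict[str, set[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(f"{path.name}:{lineno}: expected node and label")
            out.setdefault(_norm(fields[0]), set()).add(fields[1].strip())
    return {k: frozenset(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# adjacency utilities
# ---------------------------------------------------------------------------


def adjacency(net: Network, ordering: list[str] | None = None) -> np.ndarray:
    """Binary adjacency matrix A of the network in the given node ordering.

    ``ordering`` must cover every node exactly once; defaults to sorted node
    order. A is symmetric with a zero diagonal.
    """
    if ordering is None:
        ordering = net.node_list()
    ordering = [_norm(n) for n in ordering]
    if len(ordering) != len(set(ordering)) or set(ordering) != net.nodes:
        raise ValueError("ordering must cover all network nodes exactly once")
    index = {node: i for i, node in enumerate(ordering)}
    n = len(ordering)
    a = np.zeros((n, n), dtype=np.int8)
    for edge in net.edges():
        u, v = tuple(edge)
        i, j = index[u], index[v]
        a[i, j] = 1
        a[j, i] = 1
    return a


def clustering_coefficient(net: Network, v: str) -> float:
    """Local (small-world) clustering coefficient of node ``v``.

    Fraction of pairs of neighbours of ``v`` that are themselves connected;
    0 by convention when ``v`` has fewer than two neighbours.
    """
    v = _norm(v)
    if v not in net:
        raise KeyError(f"unknown node {v!r}")
    nbrs = net.neighbors(v)
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = 0
    nbr_list = sorted(nbrs)
    for i, a in enumerate(nbr_list):
        for b in nbr_list[i + 1 :]:
            if net.has_edge(a, b):
                links += 1
    return links / (k * (k - 1) / 2)
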