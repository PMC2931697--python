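import numpy as np
import pandas as pd
import pytest

from perturbnet.expr_stats import ExpressionMatrix
from perturbnet.graph_core import Network


def build_network(edges, nodes=()):
    """Network from an iterable of (u, v) pairs plus optional extra nodes."""
    net = Network()
    for n in nodes:
        net.add_node(n)
    for u, v in edges:
        net.add_edge(u, v)
    return net


def build_expression(probe_values, probe_to_gene, genotypes, compartments=("crypt",)):
    """ExpressionMatrix from a dict probe -> per-group value lists.

    ``probe_values[probe]`` maps (genotype, compartment) -> list of replicate
    values; ``genotypes`` fixes the genotype order.
    """
    samples, records = [], []
    first = next(iter(probe_values.values()))
    for genotype in genotypes:
        for comp in compartments:
            for rep in range(1, len(first[(genotype, comp)]) + 1):
                sid = f"{genotype}_{comp}_r{rep}"
                samples.append(sid)
                records.append((sid, genotype, comp, rep))
    rows = {}
    for probe, groups in probe_values.items():
        row = []
        for genotype in genotypes:
            for comp in compartments:
                row.extend(groups[(genotype, comp)])
        rows[probe] = row
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    ann = pd.DataFrame(
        records, columns=["sample", "genotype", "compartment", "replicate"]
    ).set_index("sample")
    return ExpressionMatrix(values, probe_to_gene, ann)


def simple_expression(gene_profiles, n_wt=None):
    """Single-group ExpressionMatrix: gene -> 1 probe with the given profile."""
    genes = list(gene_profiles)
    n = len(gene_profiles[genes[0]])
    samples = [f"WT_crypt_r{i + 1}" for i in range(n)]
    values = pd.DataFrame(
        {s: [gene_profiles[g][i] for g in genes] for i, s in enumerate(samples)},
        index=[f"{g}_p1" for g in genes],
    )
    ann = pd.DataFrame(
        {
            "genotype": ["WT"] * n,
            "compartment": ["crypt"] * n,
            "replicate": range(1, n + 1),
        },
        index=samples,
    )
    return ExpressionMatrix(values, {f"{g}_p1": g for g in genes}, ann)


@pytest.fixture
def triangle():
    return build_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star():
    return build_network([("HUB", leaf) for leaf in "ABCD"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
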