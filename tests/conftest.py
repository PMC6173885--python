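import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from regcircuit import (
    DiffExpressionTable,
    Edge,
    ExpressionTable,
    RegulatoryNetwork,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_network(seed, n_tf=8, n_nontf=12, n_edges=40):
    """A reproducible random directed TF->target network (test utility)."""
    rng = np.random.default_rng(seed)
    tfs = [f"T{i}" for i in range(n_tf)]
    others = [f"g{i}" for i in range(n_nontf)]
    nodes = tfs + others
    pairs = set()
    while len(pairs) < n_edges:
        a = tfs[rng.integers(len(tfs))]
        b = nodes[rng.integers(len(nodes))]
        if a != b:
            pairs.add((a, b))
    return RegulatoryNetwork(
        is_tf={n: n.startswith("T") for n in nodes},
        edges=[Edge(a, b) for a, b in sorted(pairs)],
    )


@pytest.fixture
def toy_network():
    """Small hand-checkable network: two TFs co-regulating module genes."""
    edges = [
        ("TF1", "A"), ("TF1", "B"), ("TF1", "C"),
        ("TF2", "A"), ("TF2", "B"), ("TF2", "TF1"),
        ("TF3", "C"), ("TF3", "D"),
    ]
    return RegulatoryNetwork.from_edges(edges, tfs=["TF1", "TF2", "TF3"])


def expression_from_matrix(matrix, groups, bio, tech=None):
    """Assemble an ExpressionTable from a genes-x-samples DataFrame."""
    tech = tech or [f"t{i}" for i in range(len(matrix.columns))]
    sheet = pd.DataFrame(
        {
            "group": groups,
            "biological_replicate": bio,
            "technical_replicate": tech,
        },
        index=pd.Index(matrix.columns, name="sample_id"),
    )
    return ExpressionTable(abundance=matrix, samples=sheet)


def simple_de(genes, comparison="A_vs_B", log2fc=1.0, significant=True):
    rows = [(g, comparison, log2fc, significant) for g in genes]
    return DiffExpressionTable(
        records=pd.DataFrame(
            rows, columns=["gene", "comparison", "log2fc", "significant"]
        )
    )
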