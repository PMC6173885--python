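"""Core in-memory containers for the regulatory-network pipeline.

The analysis revolves around four objects: a directed regulatory network
(transcription factor -> target edges with a per-node TF flag), an
expression table (gene x sample abundances plus a sample sheet), a
differential-expression table (per-comparison log2 fold changes and
significance calls), and plain gene sets.  All gene identifiers are opaque,
case-sensitive strings; no symbol/ID mapping is ever attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass(frozen=True)
class Edge:
    """A directed regulatory interaction (regulator -> target)."""

    regulator: str
    target: str
    evidence: Optional[str] = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.regulator, self.target)


@dataclass
class RegulatoryNetwork:
    """A directed gene regulatory network with per-node TF annotation.

    Invariants enforced on construction:

    * every edge endpoint is a declared node,
    * every edge's regulator carries ``is_tf = True``,
    * no duplicate directed edges (the same (regulator, target) pair twice).

    Self-loops are permitted and exposed via :attr:`self_loops`.
    """

    is_tf: dict[str, bool]
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.regulator not in self.is_tf:
                raise ValidationError(
                    f"edge {e.regulator}->{e.target}: regulator is not a declared node"
                )
            if e.target not in self.is_tf:
                raise ValidationError(
                    f"edge {e.regulator}->{e.target}: target is not a declared node"
                )
            if not self.is_tf[e.regulator]:
                raise ValidationError(
                    f"edge {e.regulator}->{e.target}: regulator is flagged non-TF"
                )
            if e.pair in seen:
                raise ValidationError(
                    f"duplicate directed edge {e.regulator}->{e.target}"
                )
            seen.add(e.pair)

    # -- basic views ---------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.is_tf)

    @property
    def tfs(self) -> set[str]:
        return {n for n, flag in self.is_tf.items() if flag}

    @property
    def non_tfs(self) -> set[str]:
        return {n for n, flag in self.is_tf.items() if not flag}

    @property
    def self_loops(self) -> list[Edge]:
        return [e for e in self.edges if e.regulator == e.target]

    @property
    def n_nodes(self) -> int:
        return len(self.is_tf)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}

    def __contains__(self, node: str) -> bool:
        return node in self.is_tf

    # -- conversions ---------------------------------------------------

    def to_digraph(self) -> nx.DiGraph:
        """Export as a :class:`networkx.DiGraph` with ``is_tf`` node attributes."""
        g = nx.DiGraph()
        for n, flag in self.is_tf.items():
            g.add_node(n, is_tf=flag)
        for e in self.edges:
            g.add_edge(e.regulator, e.target, evidence=e.evidence)
        return g

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        tfs: Iterable[str],
        extra_nodes: Iterable[str] = (),
    ) -> "RegulatoryNetwork":
        """Build a network from (regulator, target) pairs and a TF roster.

        Nodes are inferred from edge endpoints plus ``extra_nodes``; any node
        in ``tfs`` is flagged as a transcription factor.
        """
        tf_set = set(tfs)
        edge_objs = [Edge(a, b) for a, b in edges]
        node_set = set(extra_nodes) | tf_set
        for e in edge_objs:
            node_set.add(e.regulator)
            node_set.add(e.target)
        is_tf = {n: (n in tf_set) for n in node_set}
        return cls(is_tf=is_tf, edges=edge_objs)

    def induced(self, nodes: Iterable[str]) -> "RegulatoryNetwork":
        """Induced sub-network on ``nodes`` (all edges between retained nodes)."""
        keep = set(nodes)
        unknown = keep - self.nodes
        if unknown:
            raise ValidationError(f"induced(): unknown nodes {sorted(unknown)}")
        return RegulatoryNetwork(
            is_tf={n: self.is_tf[n] for n in keep},
            edges=[e for e in self.edges if e.regulator in keep and e.target in keep],
        )


# Required sample-sheet columns, in canonical order.
SAMPLE_COLUMNS = ("group", "biological_replicate", "technical_replicate")


@dataclass
class ExpressionTable:
    """Gene x sample abundance matrix (FPKM-like) with a sample sheet.

    ``abundance`` has genes as the row index and sample ids as columns;
    ``samples`` is indexed by sample id with columns ``group``,
    ``biological_replicate`` and ``technical_replicate``.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.samples.index.has_duplicates:
            dups = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        for col in SAMPLE_COLUMNS[:2]:
            if col in self.samples.columns and self.samples[col].isna().any():
                bad = self.samples.index[self.samples[col].isna()].tolist()
                raise ValidationError(f"samples missing {col!r}: {bad}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample sheet lacks columns {missing}")
        in_matrix = set(self.abundance.columns)
        in_sheet = set(self.samples.index)
        if in_matrix != in_sheet:
            raise ValidationError(
                "matrix/sheet sample mismatch: "
                f"only in matrix {sorted(in_matrix - in_sheet)}, "
                f"only in sheet {sorted(in_sheet - in_matrix)}"
            )
        if (self.abundance.to_numpy() < 0).any():
            raise ValidationError("negative abundance values present")

    @property
    def genes(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.samples["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of_group(self, group: str) -> list[str]:
        sel = self.samples.index[self.samples["group"] == group]
        return list(sel)


@dataclass
class DiffExpressionTable:
    """Per-comparison differential-expression records.

    ``records`` columns: ``gene``, ``comparison``, ``log2fc`` (finite float),
    ``significant`` (bool) and optionally ``q``.  One record per
    (gene, comparison).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "comparison", "log2fc", "significant"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"DE table lacks columns {sorted(missing)}")
        if len(self.records):
            import numpy as np

            lfc = self.records["log2fc"].to_numpy(dtype=float)
            if not np.isfinite(lfc).all():
                raise ValidationError("non-finite log2fc in DE table")
            dup = self.records.duplicated(subset=["gene", "comparison"])
            if dup.any():
                pairs = self.records.loc[dup, ["gene", "comparison"]].values.tolist()
                raise ValidationError(f"duplicate (gene, comparison) records: {pairs}")

    def comparisons(self) -> list[str]:
        return sorted(self.records["comparison"].unique())

    def for_comparison(self, comparison: str) -> pd.DataFrame:
        return self.records[self.records["comparison"] == comparison]

    def significant_genes(self, comparison: str) -> set[str]:
        sub = self.for_comparison(comparison)
        return set(sub.loc[sub["significant"].astype(bool), "gene"])

    @property
    def n_significant(self) -> int:
        return int(self.records["significant"].astype(bool).sum())


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    members: frozenset[str]
    description: str = ""

    @classmethod
    def from_iterable(
        cls, name: str, members: Iterable[str], description: str = ""
    ) -> "GeneSet":
        return cls(name=name, members=frozenset(members), description=description)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)
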