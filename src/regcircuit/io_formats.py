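"""Readers and writers for the pipeline's external file formats.

All text formats are UTF-8.  Tab-separated files may contain ``#`` comment
lines, which are ignored; no quoting is supported.  Gene identifiers are
carried verbatim (opaque, case-sensitive).

Formats:

* edge list TSV: ``regulator<TAB>target[<TAB>evidence]``
* node attribute TSV: ``node_id<TAB>is_tf`` with ``is_tf`` in {0, 1}
* SIF: ``regulator<TAB>regulates<TAB>target`` (Cytoscape-compatible)
* expression matrix TSV (genes x samples) + sample sheet CSV
* DE table TSV: ``gene, comparison, log2fc, q, significant``
* gene sets: one id per line, or GMT (``name<TAB>description<TAB>id...``)
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import pandas as pd

from .model import (
    DiffExpressionTable,
    Edge,
    ExpressionTable,
    GeneSet,
    RegulatoryNetwork,
    SAMPLE_COLUMNS,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised for malformed input; carries file and line number in the message."""


def _data_lines(path: PathLike):
    """Yield (1-based line number, stripped line) skipping blanks and comments."""
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


# ---------------------------------------------------------------------------
# Regulatory networks
# ---------------------------------------------------------------------------

def read_network(edge_list_path: PathLike, node_attr_path: PathLike) -> RegulatoryNetwork:
    """Read a directed regulatory network from an edge list plus node attributes.

    Duplicated directed edges are stored once; the number of duplicates is
    logged.  Nodes listed in the attribute file but absent from the edge list
    are ignored with a warning.  An edge whose regulator is flagged non-TF is
    a validation error.
    """
    is_tf: dict[str, bool] = {}
    for i, line in _data_lines(node_attr_path):
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ParseError(
                f"{node_attr_path}:{i}: expected 'node_id<TAB>0|1', got {line!r}"
            )
        is_tf[parts[0]] = parts[1] == "1"

    declared = set(is_tf)
    edges: list[Edge] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for i, line in _data_lines(edge_list_path):
        parts = line.split("\t")
        if len(parts) not in (2, 3) or not parts[0] or not parts[1]:
            raise ParseError(
                f"{edge_list_path}:{i}: expected 'regulator<TAB>target[<TAB>evidence]', "
                f"got {line!r}"
            )
        reg, tgt = parts[0], parts[1]
        evidence = parts[2] if len(parts) == 3 else None
        if (reg, tgt) in seen:
            n_dup += 1
            continue
        seen.add((reg, tgt))
        for node in (reg, tgt):
            is_tf.setdefault(node, False)
        # Edge sources must be TFs.  An unannotated regulator is promoted
        # (its position implies TF status); an explicitly non-TF flag in the
        # attribute file wins and fails validation below.
        if reg not in declared:
            is_tf[reg] = True
        edges.append(Edge(reg, tgt, evidence))
    if n_dup:
        logger.warning("read_network: deduplicated %d repeated edge(s)", n_dup)
    touched = {e.regulator for e in edges} | {e.target for e in edges}
    orphans = declared - touched
    if orphans:
        logger.warning(
            "read_network: %d attribute-file node(s) absent from the edge list "
            "ignored: %s", len(orphans), sorted(orphans)[:10],
        )
        for n in orphans:
            del is_tf[n]
    return RegulatoryNetwork(is_tf=is_tf, edges=edges)


def write_network(net: RegulatoryNetwork, edge_list_path: PathLike,
                  node_attr_path: PathLike) -> None:
    """Write the edge-list + node-attribute representation of ``net``."""
    with open(edge_list_path, "w", encoding="utf-8") as fh:
        for e in net.edges:
            if e.evidence is not None:
                fh.write(f"{e.regulator}\t{e.target}\t{e.evidence}\n")
            else:
                fh.write(f"{e.regulator}\t{e.target}\n")
    with open(node_attr_path, "w", encoding="utf-8") as fh:
        for n in sorted(net.is_tf):
            fh.write(f"{n}\t{int(net.is_tf[n])}\n")


def write_sif(net: RegulatoryNetwork, path: PathLike,
              node_attr_path: PathLike | None = None) -> None:
    """Export as SIF (``regulator<TAB>regulates<TAB>target``).

    SIF cannot encode isolated nodes; when ``node_attr_path`` is given, a
    node-attribute sidecar preserving the full node roster (with TF flags)
    is written alongside.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for e in net.edges:
            fh.write(f"{e.regulator}\tregulates\t{e.target}\n")
    if node_attr_path is not None:
        with open(node_attr_path, "w", encoding="utf-8") as fh:
            for n in sorted(net.is_tf):
                fh.write(f"{n}\t{int(net.is_tf[n])}\n")


def read_sif(path: PathLike, node_attr_path: PathLike | None = None) -> RegulatoryNetwork:
    """Read a SIF file written by :func:`write_sif`.

    Without a sidecar, TF status is inferred from edge sources and isolated
    nodes are lost (a SIF limitation, not a bug).
    """
    edges: list[tuple[str, str]] = []
    for i, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 3 or parts[1] != "regulates":
            raise ParseError(f"{path}:{i}: expected 'a<TAB>regulates<TAB>b', got {line!r}")
        edges.append((parts[0], parts[2]))
    if node_attr_path is None:
        tfs = {a for a, _ in edges}
        return RegulatoryNetwork.from_edges(edges, tfs=tfs)
    is_tf: dict[str, bool] = {}
    for i, line in _data_lines(node_attr_path):
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ParseError(f"{node_attr_path}:{i}: expected 'node<TAB>0|1', got {line!r}")
        is_tf[parts[0]] = parts[1] == "1"
    return RegulatoryNetwork(is_tf=is_tf, edges=[Edge(a, b) for a, b in edges])


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression(matrix_path: PathLike, samplesheet_path: PathLike) -> ExpressionTable:
    """Read a genes-x-samples TSV matrix and its sample sheet CSV.

    The sample sheet must have columns ``sample_id``, ``group``,
    ``biological_replicate`` and ``technical_replicate``.  The matrix columns
    and the sheet's sample ids must match exactly; negative abundances are
    rejected.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    sheet = pd.read_csv(samplesheet_path)
    if "sample_id" not in sheet.columns:
        raise ParseError(f"{samplesheet_path}: sample sheet lacks 'sample_id' column")
    sheet = sheet.set_index("sample_id")
    sheet.index = sheet.index.astype(str)
    missing = [c for c in SAMPLE_COLUMNS if c not in sheet.columns]
    if missing:
        raise ParseError(f"{samplesheet_path}: sample sheet lacks columns {missing}")
    return ExpressionTable(abundance=matrix, samples=sheet[list(SAMPLE_COLUMNS)])


def write_expression(expr: ExpressionTable, matrix_path: PathLike,
                     samplesheet_path: PathLike) -> None:
    expr.abundance.to_csv(matrix_path, sep="\t")
    out = expr.samples.copy()
    out.index.name = "sample_id"
    out.to_csv(samplesheet_path)


# ---------------------------------------------------------------------------
# DE tables and gene sets
# ---------------------------------------------------------------------------

def read_de_table(path: PathLike) -> DiffExpressionTable:
    """Read a DE table TSV with header (gene, comparison, log2fc[, q], significant)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "comparison", "log2fc", "significant"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: DE table lacks columns {sorted(missing)}")
    try:
        df["log2fc"] = df["log2fc"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric log2fc value ({exc})") from None
    df["gene"] = df["gene"].astype(str)
    df["significant"] = df["significant"].astype(bool)
    return DiffExpressionTable(records=df)


def write_de_table(de: DiffExpressionTable, path: PathLike) -> None:
    de.records.to_csv(path, sep="\t", index=False)


def read_gene_set(path: PathLike, name: str | None = None) -> GeneSet:
    """Read a gene set: one id per line (``name`` defaults to the file stem).

    Repeated ids are deduplicated with a logged warning.
    """
    ids: list[str] = []
    for _, line in _data_lines(path):
        ids.append(line.strip())
    n_dup = len(ids) - len(set(ids))
    if n_dup:
        logger.warning("read_gene_set(%s): deduplicated %d repeated id(s)", path, n_dup)
    return GeneSet.from_iterable(name or Path(path).stem, ids)


def read_gmt(path: PathLike) -> list[GeneSet]:
    """Read a GMT file (``name<TAB>description<TAB>gene1<TAB>gene2...``)."""
    sets: list[GeneSet] = []
    for i, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{i}: GMT line needs name, description, >=1 gene")
        sets.append(GeneSet.from_iterable(parts[0], parts[2:], description=parts[1]))
    return sets


def write_gene_set(gs: GeneSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in gs.sorted_members():
            fh.write(g + "\n")
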