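"""Condition a background regulatory network on embryo expression evidence.

The background TF->target network is reduced to a "general network" by
keeping an interaction only when

(a) the regulator's transcript is detected in the embryos,
(b) the target is called differentially expressed in the comparison of
    interest, and
(c) the magnitude of the target's per-biological-replicate log2 fold change
    reaches a threshold (0.4 by default).

Detection and the fold-change criterion are evaluated per biological
replicate (technical replicates averaged first) and combined across
replicates with a configurable rule: ``"all"`` requires the criterion in
every replicate (intersection), ``"any"`` in at least one (union).  Nodes
left without any retained incident edge are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    DiffExpressionTable,
    ExpressionTable,
    RegulatoryNetwork,
    SAMPLE_COLUMNS,
    ValidationError,
)

#: Reasons an edge can be dropped, in evaluation order (first failure wins).
DROP_REASONS = ("regulator-detection", "target-de-significance", "target-fold-change")


@dataclass(frozen=True)
class FilterCriteria:
    """Edge-retention thresholds for building the general network.

    ``min_abs_log2fc``: fold-change magnitude the target must reach per
    replicate (log2 units).  ``detection_threshold``: abundance strictly
    above this counts as detected (0 means any positive FPKM).
    ``replicate_rule``: how per-replicate decisions combine ("all" | "any").
    ``pseudocount`` is added to numerator and denominator of the fold
    change; the default 0 lets division by zero produce +/-inf log2fc,
    which compares correctly against the threshold.
    ``require_regulator_de``: also require the regulator to be a
    differentially expressed gene (off by default; the regulator need only
    be detected).
    """

    min_abs_log2fc: float = 0.4
    detection_threshold: float = 0.0
    replicate_rule: str = "all"
    pseudocount: float = 0.0
    require_regulator_de: bool = False

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ValidationError("min_abs_log2fc must be >= 0")
        if self.replicate_rule not in ("all", "any"):
            raise ValidationError("replicate_rule must be 'all' or 'any'")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")


@dataclass
class EdgeFilterReport:
    """Per-edge audit of the network filter.

    ``per_edge`` has one row per input edge with columns ``regulator``,
    ``target``, ``retained`` and ``reason`` (the first failed criterion, or
    "" when retained).  ``missing_from_expression`` lists network genes the
    expression table does not cover (treated as not detected / failing the
    fold-change criterion, not as errors).
    """

    per_edge: pd.DataFrame
    n_input: int
    n_retained: int
    missing_from_expression: set[str] = field(default_factory=set)

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_retained

    def reason_counts(self) -> dict[str, int]:
        dropped = self.per_edge[~self.per_edge["retained"]]
        counts = dropped["reason"].value_counts().to_dict()
        return {r: int(counts.get(r, 0)) for r in DROP_REASONS}


def average_technical_replicates(expr: ExpressionTable) -> ExpressionTable:
    """Collapse technical replicates by arithmetic mean.

    Returns a table with one column per biological replicate (named by the
    biological replicate id), groups preserved.  A biological replicate must
    have at least one technical replicate (guaranteed by construction; an
    empty table raises).
    """
    if not len(expr.samples):
        raise ValidationError("expression table has no samples")
    sheet = expr.samples
    groups: dict[str, str] = {}
    cols: dict[str, list[str]] = {}
    for sid, row in sheet.iterrows():
        bio = str(row["biological_replicate"])
        cols.setdefault(bio, []).append(sid)
        prev = groups.setdefault(bio, row["group"])
        if prev != row["group"]:
            raise ValidationError(
                f"biological replicate {bio!r} spans groups {prev!r} and {row['group']!r}"
            )
    data = {bio: expr.abundance[sids].mean(axis=1) for bio, sids in cols.items()}
    order = list(dict.fromkeys(str(r) for r in sheet["biological_replicate"]))
    matrix = pd.DataFrame(data)[order]
    new_sheet = pd.DataFrame(
        {
            "group": [groups[b] for b in order],
            "biological_replicate": order,
            "technical_replicate": ["avg"] * len(order),
        },
        index=pd.Index(order, name="sample_id"),
    )
    return ExpressionTable(abundance=matrix, samples=new_sheet)


def per_replicate_log2fc(
    expr: ExpressionTable,
    comparison: tuple[str, str],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-replicate fold changes of group B against the group-A mean.

    For every gene and every biological replicate of ``comparison[1]``::

        log2fc = log2((abundance_B_replicate + pc) / (mean abundance over A + pc))

    Technical replicates are averaged first.  Returns a genes x B-replicates
    DataFrame; with ``pseudocount == 0`` zero denominators/numerators yield
    +/-inf (and 0/0 yields NaN), which is intentional.
    """
    group_a, group_b = comparison
    avg = average_technical_replicates(expr)
    for g in (group_a, group_b):
        if g not in set(avg.samples["group"]):
            raise ValidationError(f"group {g!r} absent from expression table")
    a_cols = avg.samples_of_group(group_a)
    b_cols = avg.samples_of_group(group_b)
    ref = avg.abundance[a_cols].mean(axis=1).to_numpy() + pseudocount
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for col in b_cols:
            num = avg.abundance[col].to_numpy() + pseudocount
            out[col] = np.log2(num) - np.log2(ref)
    return pd.DataFrame(out, index=avg.abundance.index)


def _rule(values: np.ndarray, rule: str) -> bool:
    return bool(values.all()) if rule == "all" else bool(values.any())


def filter_network(
    bg: RegulatoryNetwork,
    expr: ExpressionTable,
    de: DiffExpressionTable,
    crit: FilterCriteria = FilterCriteria(),
    comparison: Optional[tuple[str, str]] = None,
) -> tuple[RegulatoryNetwork, EdgeFilterReport]:
    """Reduce ``bg`` to the general network supported by expression evidence.

    ``comparison`` names the (reference group, test group) pair whose
    replicates drive detection and fold changes; it must match a comparison
    label ``"<A>_vs_<B>"`` present in ``de`` (when ``de`` holds a single
    comparison, it may be omitted and is inferred).

    Genes absent from the expression table are treated as not detected (as
    regulators) or as failing the fold-change criterion (as targets) and are
    listed in the report, not raised as errors.
    """
    if comparison is None:
        labels = de.comparisons()
        if len(labels) != 1:
            raise ValidationError(
                f"comparison is required when the DE table holds {len(labels)} comparisons"
            )
        group_a, group_b = labels[0].split("_vs_")
    else:
        group_a, group_b = comparison
    label = f"{group_a}_vs_{group_b}"
    if label not in de.comparisons():
        raise ValidationError(f"DE table has no comparison {label!r}")

    avg = average_technical_replicates(expr)
    rep_cols = [
        c
        for c in avg.abundance.columns
        if avg.samples.loc[c, "group"] in (group_a, group_b)
    ]
    expr_genes = set(avg.abundance.index)
    detected: dict[str, bool] = {}
    for gene in expr_genes:
        vals = avg.abundance.loc[gene, rep_cols].to_numpy(dtype=float)
        detected[gene] = _rule(vals > crit.detection_threshold, crit.replicate_rule)

    lfc = per_replicate_log2fc(expr, (group_a, group_b), crit.pseudocount)
    fc_ok: dict[str, bool] = {}
    for gene in expr_genes:
        vals = np.abs(lfc.loc[gene].to_numpy(dtype=float))
        vals = np.nan_to_num(vals, nan=0.0)  # 0/0 counts as no change
        fc_ok[gene] = _rule(vals >= crit.min_abs_log2fc, crit.replicate_rule)

    significant = de.significant_genes(label)

    rows = []
    missing: set[str] = set()
    for e in bg.edges:
        reason = ""
        if e.regulator not in expr_genes:
            missing.add(e.regulator)
        if e.target not in expr_genes:
            missing.add(e.target)
        if not detected.get(e.regulator, False):
            reason = "regulator-detection"
        elif e.target not in significant or (
            crit.require_regulator_de and e.regulator not in significant
        ):
            reason = "target-de-significance"
        elif not fc_ok.get(e.target, False):
            reason = "target-fold-change"
        rows.append((e.regulator, e.target, reason == "", reason))

    per_edge = pd.DataFrame(rows, columns=["regulator", "target", "retained", "reason"])
    kept_edges = [e for e, r in zip(bg.edges, rows) if r[2]]
    kept_nodes = {e.regulator for e in kept_edges} | {e.target for e in kept_edges}
    filtered = RegulatoryNetwork(
        is_tf={n: bg.is_tf[n] for n in kept_nodes}, edges=kept_edges
    )
    report = EdgeFilterReport(
        per_edge=per_edge,
        n_input=bg.n_edges,
        n_retained=len(kept_edges),
        missing_from_expression=missing,
    )
    return filtered, report
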