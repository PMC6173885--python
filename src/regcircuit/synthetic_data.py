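"""Synthetic networks, expression and qPCR data with a planted circuit.

The generator emulates the statistical structure the pipeline assumes so
that every stage is testable without downloads:

* a sparse random directed TF->target background network, into which a
  master-regulator circuit is planted: a master TF regulating a small set
  of integrator TFs and, together with the integrators, every gene of two
  disjoint response modules (a "neural-tube-like" module suppressed when
  master activity is high, and a "lipid-like" module elevated by it);
* three sample groups (WT, KO-N, KO-NTD) x 3 biological replicates.  Each
  replicate draws a latent master activity ``a ~ Normal(group mean, 1)``
  with group means (0, 0, 1.5) — the divergent group mirrors an embryo
  pool with elevated master-regulator signalling.  Module gene means scale
  by ``2**(+-effect * a)`` and all abundances receive multiplicative
  lognormal measurement noise;
* a differential-expression table derived from the true planted effects
  (the pipeline consumes DE calls, it does not make them): per comparison,
  log2FC is the expected group difference and significance means
  |log2FC| >= 0.4;
* Ct-scale qPCR data consistent with the Pfaffl model (exact inversion in
  the noiseless case) with Normal Ct noise.

All generators are pure functions of (config, seed); no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    DiffExpressionTable,
    Edge,
    ExpressionTable,
    RegulatoryNetwork,
    ValidationError,
)

DEFAULT_GROUPS = (("WT", 3), ("KO-N", 3), ("KO-NTD", 3))
DEFAULT_ACTIVITY_MEANS = {"WT": 0.0, "KO-N": 0.0, "KO-NTD": 1.5}


@dataclass(frozen=True)
class CircuitSpec:
    """The planted master-regulator circuit.

    ``module_down`` genes are suppressed when master activity is high
    (neural-tube-like); ``module_up`` genes are elevated (lipid-like).
    Effect sizes are log2 units per unit of latent activity and act with
    opposite sign on the two modules.  ``noise_sd`` is the sd of the
    multiplicative lognormal measurement noise on the natural-log scale.
    """

    master: str = "masterTF"
    integrators: tuple[str, ...] = ("integratorTF1", "integratorTF2")
    module_down: tuple[str, ...] = ("neural1", "neural2", "neural3", "neural4")
    module_up: tuple[str, ...] = ("lipid1", "lipid2", "lipid3", "lipid4")
    effect_down: float = 1.0
    effect_up: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if set(self.module_down) & set(self.module_up):
            raise ValidationError("modules must be disjoint")
        if len(self.integrators) < 1:
            raise ValidationError("at least one integrator TF is required")
        if self.effect_down < 0 or self.effect_up < 0:
            raise ValidationError(
                "effect sizes are magnitudes; signs are fixed by module role"
            )

    @property
    def module_genes(self) -> tuple[str, ...]:
        return self.module_down + self.module_up

    @property
    def circuit_tfs(self) -> tuple[str, ...]:
        return (self.master,) + self.integrators


@dataclass(frozen=True)
class SimulationConfig:
    """Size and sampling design of a synthetic study.

    Defaults mirror a three-group embryo-pool design (WT / KO-N / KO-NTD,
    three pooled biological replicates each) with the divergent group
    carrying the highest latent master activity.
    """

    n_tf: int = 30
    n_nontf: int = 90
    mean_out_degree: float = 3.0
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    technical_replicates: int = 1
    activity_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_MEANS)
    )
    activity_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tf < 1 or self.n_nontf < 1 or self.technical_replicates < 1:
            raise ValidationError("counts must be positive")
        if any(n < 1 for _, n in self.groups):
            raise ValidationError("replicate counts must be positive")
        missing = [g for g, _ in self.groups if g not in self.activity_means]
        if missing:
            raise ValidationError(f"activity mean missing for groups {missing}")


def generate_network(cfg: SimulationConfig, circuit: CircuitSpec) -> RegulatoryNetwork:
    """A random background network with the circuit edges guaranteed.

    Node budget: ``n_tf`` TFs (the master and integrators first) and
    ``n_nontf`` non-TFs (module genes first).  Each TF draws a
    Poisson(mean out-degree) number of random targets; circuit edges —
    master -> each integrator, and master plus every integrator -> every
    module gene — are then added, which puts every module gene within two
    undirected hops of the master and gives every pair of module genes at
    least two common TF regulators.
    """
    if len(circuit.circuit_tfs) > cfg.n_tf:
        raise ValidationError("circuit TFs exceed the TF budget")
    if len(circuit.module_genes) > cfg.n_nontf:
        raise ValidationError("module genes exceed the non-TF budget")
    rng = np.random.default_rng(cfg.rng_seed)
    tfs = list(circuit.circuit_tfs) + [
        f"tf{i:03d}" for i in range(cfg.n_tf - len(circuit.circuit_tfs))
    ]
    non_tfs = list(circuit.module_genes) + [
        f"g{i:03d}" for i in range(cfg.n_nontf - len(circuit.module_genes))
    ]
    nodes = tfs + non_tfs

    pairs: set[tuple[str, str]] = set()
    for tf in tfs:
        k = min(int(rng.poisson(cfg.mean_out_degree)), len(nodes) - 1)
        if k == 0:
            continue
        candidates = [n for n in nodes if n != tf]
        targets = rng.choice(len(candidates), size=k, replace=False)
        for t in targets:
            pairs.add((tf, candidates[int(t)]))
    for integ in circuit.integrators:
        pairs.add((circuit.master, integ))
    for gene in circuit.module_genes:
        pairs.add((circuit.master, gene))
        for integ in circuit.integrators:
            pairs.add((integ, gene))

    edges = [Edge(a, b, "simulated") for a, b in sorted(pairs)]
    is_tf = {n: (n in set(tfs)) for n in nodes}
    return RegulatoryNetwork(is_tf=is_tf, edges=edges)


def _gene_effect(gene: str, circuit: CircuitSpec) -> float:
    if gene in circuit.module_up:
        return circuit.effect_up
    if gene in circuit.module_down:
        return -circuit.effect_down
    return 0.0


def simulate_expression(
    net: RegulatoryNetwork, cfg: SimulationConfig, circuit: CircuitSpec
) -> tuple[ExpressionTable, DiffExpressionTable]:
    """Draw abundances for every network gene and the matching true DE table.

    Per biological replicate a latent activity is drawn; module genes
    respond multiplicatively (``2**(sign * effect * a)``) around a fixed
    per-gene lognormal baseline, then lognormal measurement noise is
    applied per technical replicate.  The DE table holds, for each pairwise
    group comparison "A_vs_B", the expected log2 fold change
    ``sign * effect * (mean_B - mean_A)`` with significance defined as
    |log2FC| >= 0.4.
    """
    missing = set(circuit.module_genes) - net.nodes
    if missing:
        raise ValidationError(f"circuit genes absent from network: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, 1)))
    genes = sorted(net.nodes)
    baseline = pd.Series(rng.lognormal(mean=2.0, sigma=1.0, size=len(genes)),
                         index=genes)

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    effects = np.array([_gene_effect(g, circuit) for g in genes])
    for group, n_bio in cfg.groups:
        for b in range(1, n_bio + 1):
            a = rng.normal(cfg.activity_means[group], cfg.activity_sd)
            mean_vec = baseline.to_numpy() * np.power(2.0, effects * a)
            for t in range(1, cfg.technical_replicates + 1):
                noise = rng.lognormal(mean=0.0, sigma=circuit.noise_sd,
                                      size=len(genes))
                sid = f"{group}_r{b}_t{t}"
                columns[sid] = mean_vec * noise
                sheet_rows.append((sid, group, f"{group}_r{b}", f"t{t}"))

    abundance = pd.DataFrame(columns, index=genes)
    sheet = pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "group", "biological_replicate", "technical_replicate"],
    ).set_index("sample_id")
    expr = ExpressionTable(abundance=abundance, samples=sheet)

    group_names = [g for g, _ in cfg.groups]
    records = []
    for i, ga in enumerate(group_names):
        for gb in group_names[i + 1:]:
            delta = cfg.activity_means[gb] - cfg.activity_means[ga]
            label = f"{ga}_vs_{gb}"
            for gene, eff in zip(genes, effects):
                lfc = eff * delta
                records.append((gene, label, lfc, abs(lfc) >= 0.4))
    de = DiffExpressionTable(
        records=pd.DataFrame(
            records, columns=["gene", "comparison", "log2fc", "significant"]
        )
    )
    return expr, de


def simulate_qpcr(
    true_ratios: Mapping[str, float],
    efficiencies: Mapping[str, float],
    reference: str = "refgene",
    n_per_group: tuple[int, int] = (3, 3),
    groups: tuple[str, str] = ("control", "treated"),
    ct_noise_sd: float = 0.0,
    base_ct: float = 22.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Ct-scale qPCR measurements consistent with the Pfaffl model.

    For each target gene the treated-group Ct is shifted by
    ``-log(ratio)/log(E)`` relative to control while the reference gene is
    flat, so on noiseless data the Pfaffl ratio recovers ``true_ratios``
    exactly.  Returns a long table (sample_id, group, gene, ct).
    """
    for g, ratio in true_ratios.items():
        if ratio <= 0:
            raise ValidationError(f"true ratio for {g!r} must be positive")
        if g not in efficiencies:
            raise ValidationError(f"no efficiency for gene {g!r}")
    if reference not in efficiencies:
        raise ValidationError(f"no efficiency for reference {reference!r}")
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 2)))
    rows = []
    samples = [(groups[0], i) for i in range(1, n_per_group[0] + 1)] + [
        (groups[1], i) for i in range(1, n_per_group[1] + 1)
    ]
    gene_list = list(true_ratios) + [reference]
    for gene in gene_list:
        e = efficiencies[gene]
        if not 1.0 < e <= 2.2:
            raise ValidationError(f"efficiency for {gene!r} outside (1, 2.2]")
        shift = 0.0
        if gene != reference:
            shift = -np.log(true_ratios[gene]) / np.log(e)
        for group, i in samples:
            ct = base_ct + (shift if group == groups[1] else 0.0)
            if ct_noise_sd > 0:
                ct += rng.normal(0.0, ct_noise_sd)
            rows.append((f"{group}_{i}", group, gene, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
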