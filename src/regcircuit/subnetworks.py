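"""Seed-node subnetworks and their shared transcription factors.

A subnetwork is grown from a gene of interest (the seed) by taking its
neighbors up to two levels, ignoring edge direction (the regulators of a
non-TF seed would otherwise be unreachable), then pruned in two ordered
steps: (1) every node with fewer than two incident edges inside the
subnetwork is removed (the seed included), (2) every remaining non-TF node
except the seed is removed.  Induced edges are recomputed after each step.
Degree pruning is a single pass, not iterated to a fixed point; an
``iterate`` flag exposes fixed-point pruning for sensitivity analysis.

The candidate regulators of a tuple of seeds are the TFs present in every
member subnetwork (the seeds themselves excluded by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .model import RegulatoryNetwork, ValidationError


@dataclass
class Subnetwork:
    """A pruned seed neighborhood with a provenance trail of node counts."""

    seed: str
    network: RegulatoryNetwork
    provenance: list[tuple[str, int]] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return self.network.nodes

    @property
    def tfs(self) -> set[str]:
        return self.network.tfs

    def __contains__(self, node: str) -> bool:
        return node in self.network


@dataclass(frozen=True)
class SharedTFResult:
    """TFs common to every subnetwork of a seed tuple."""

    seeds: tuple[str, ...]
    shared_tfs: frozenset[str]

    @property
    def k(self) -> int:
        return len(self.shared_tfs)


def two_level_neighborhood(
    net: RegulatoryNetwork, seed: str, directed: bool = False
) -> Subnetwork:
    """Induced subgraph on the seed plus its neighbors up to two levels.

    Neighbors are taken on the undirected projection unless ``directed``
    (then only downstream nodes are expanded).  All edges between retained
    nodes are kept.
    """
    if seed not in net:
        raise ValidationError(f"seed {seed!r} is not a node of the network")
    g = net.to_digraph()
    search = g if directed else g.to_undirected(as_view=True)
    ball = {seed}
    frontier = {seed}
    for _ in range(2):
        nxt = set()
        for v in frontier:
            nxt.update(search.neighbors(v))
        frontier = nxt - ball
        ball |= frontier
    sub = Subnetwork(seed=seed, network=net.induced(ball))
    sub.provenance.append(("two_level_neighborhood", len(ball)))
    return sub


def _incident_degree(net: RegulatoryNetwork) -> dict[str, int]:
    """In+out incident edge count per node (each stored directed edge counts
    once per endpoint; a self-loop therefore contributes two)."""
    deg = {n: 0 for n in net.is_tf}
    for e in net.edges:
        deg[e.regulator] += 1
        deg[e.target] += 1
    return deg


def prune_subnetwork(sub: Subnetwork, iterate: bool = False) -> Subnetwork:
    """Apply the two-step pruning recipe, in order.

    Step 1 removes every node whose incident edge count within the
    subnetwork is below two — the seed enjoys no exemption here, so a
    loosely connected seed can prune itself away (an empty result is legal
    and recorded in the provenance).  Step 2 removes remaining non-TF nodes,
    sparing the seed.  With ``iterate=True`` step 1 is repeated to a fixed
    point before step 2.
    """
    net = sub.network
    provenance = list(sub.provenance)

    while True:
        deg = _incident_degree(net)
        keep = {n for n, d in deg.items() if d >= 2}
        removed = net.n_nodes - len(keep)
        net = net.induced(keep)
        provenance.append(("degree_prune", net.n_nodes))
        if not iterate or removed == 0:
            break

    keep = {n for n in net.is_tf if net.is_tf[n] or n == sub.seed}
    net = net.induced(keep)
    provenance.append(("tf_prune", net.n_nodes))
    return Subnetwork(seed=sub.seed, network=net, provenance=provenance)


def build_seed_subnetwork(
    net: RegulatoryNetwork, seed: str, directed: bool = False, iterate: bool = False
) -> Subnetwork:
    """Two-level neighborhood followed by pruning (the full recipe)."""
    return prune_subnetwork(two_level_neighborhood(net, seed, directed=directed),
                            iterate=iterate)


def shared_tfs(
    subs: Sequence[Subnetwork], include_seeds: bool = False
) -> SharedTFResult:
    """Intersect the TFs of two or more subnetworks.

    Seeds are excluded from the intersection by default, even when a seed
    is itself a TF: the question is which regulators act on all the seeds,
    and a seed trivially contained in its own subnetwork is uninformative.
    ``include_seeds=True`` reports the inclusive variant.
    """
    if len(subs) < 2:
        raise ValidationError("shared_tfs needs at least two subnetworks")
    seeds = tuple(s.seed for s in subs)
    inter = set(subs[0].nodes)
    for s in subs[1:]:
        inter &= s.nodes
    shared = {n for n in inter if subs[0].network.is_tf.get(n, False)}
    # is_tf flags agree across subnetworks of one parent; use any member's.
    if not include_seeds:
        shared -= set(seeds)
    return SharedTFResult(seeds=seeds, shared_tfs=frozenset(shared))
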