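"""Empirical null distribution of shared-TF counts over seed quadruplets.

Every unordered set of four nodes in the general network is treated as a
candidate seed quadruplet; for each one the four seed subnetworks are built
with the exact same recipe used for the observed genes of interest, and the
number of TFs shared by all four is recorded.  The histogram of those counts
is the empirical null, and the tail probability of the observed count is its
exact probability of occurrence under random seed choice.

Two enumeration modes mirror the two null designs: ``any_nodes`` (all
C(n, 4) quadruplets) and ``one_tf_three_nontf`` (one TF with three non-TFs,
modelling a seed set like three apolipoprotein genes plus one TF gene).
When the exhaustive count exceeds ``max_quadruplets``, quadruplets are
sampled uniformly without replacement with a recorded seed; exhaustive
enumeration is the default and the provenance always records which ran.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .model import RegulatoryNetwork, ValidationError
from .subnetworks import build_seed_subnetwork

MODES = ("any_nodes", "one_tf_three_nontf")


@dataclass
class NullDistribution:
    """Histogram of shared-TF counts k over evaluated quadruplets."""

    mode: str
    counts: dict[int, int]
    total: int
    sampled: bool
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValidationError("null distribution counts do not sum to total")

    def frequencies(self) -> dict[int, float]:
        return {k: c / self.total for k, c in sorted(self.counts.items())}

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.counts)
        return pd.DataFrame(
            {
                "k": ks,
                "count": [self.counts[k] for k in ks],
                "frequency": [self.counts[k] / self.total for k in ks],
            }
        )


def count_quadruplets(net: RegulatoryNetwork, mode: str = "any_nodes") -> int:
    """Number of quadruplets the chosen mode enumerates."""
    _check_mode(net, mode)
    if mode == "any_nodes":
        return comb(net.n_nodes, 4)
    return len(net.tfs) * comb(len(net.non_tfs), 3)


def _check_mode(net: RegulatoryNetwork, mode: str) -> None:
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "any_nodes" and net.n_nodes < 4:
        raise ValidationError("any_nodes mode needs at least 4 nodes")
    if mode == "one_tf_three_nontf" and (len(net.tfs) < 1 or len(net.non_tfs) < 3):
        raise ValidationError("one_tf_three_nontf mode needs >=1 TF and >=3 non-TFs")


def enumerate_quadruplets(
    net: RegulatoryNetwork, mode: str = "any_nodes"
) -> Iterator[tuple[str, ...]]:
    """Yield quadruplets as sorted tuples in deterministic lexicographic order."""
    from itertools import combinations

    _check_mode(net, mode)
    if mode == "any_nodes":
        for quad in combinations(sorted(net.nodes), 4):
            yield quad
    else:
        non_tfs = sorted(net.non_tfs)
        for tf in sorted(net.tfs):
            for trio in combinations(non_tfs, 3):
                yield tuple(sorted((tf,) + trio))


def _unrank_combination(rank: int, n: int, k: int) -> tuple[int, ...]:
    """The rank-th (0-based) k-combination of range(n) in lexicographic order."""
    out = []
    x = 0
    for depth in range(k, 0, -1):
        while True:
            block = comb(n - x - 1, depth - 1)
            if rank < block:
                break
            rank -= block
            x += 1
        out.append(x)
        x += 1
    return tuple(out)


def _sample_indices(total: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample without replacement from range(total); total may be huge."""
    if total <= 4 * size:
        return rng.permutation(total)[:size]
    chosen: set[int] = set()
    while len(chosen) < size:
        draw = rng.integers(0, total, size=size - len(chosen))
        chosen.update(int(v) for v in draw)
    return np.array(sorted(chosen))


def _quadruplet_at(
    index: int, mode: str, nodes: list[str], tfs: list[str], non_tfs: list[str]
) -> tuple[str, ...]:
    if mode == "any_nodes":
        combo = _unrank_combination(index, len(nodes), 4)
        return tuple(nodes[i] for i in combo)
    per_tf = comb(len(non_tfs), 3)
    tf = tfs[index // per_tf]
    trio = _unrank_combination(index % per_tf, len(non_tfs), 3)
    return tuple(sorted((tf,) + tuple(non_tfs[i] for i in trio)))


def shared_tf_distribution(
    net: RegulatoryNetwork,
    mode: str = "any_nodes",
    max_quadruplets: Optional[int] = None,
    rng_seed: Optional[int] = None,
) -> NullDistribution:
    """Shared-TF count histogram over quadruplets of the network.

    Each node's pruned seed subnetwork is built once (with the same recipe
    as the observed analysis) and memoized; a quadruplet's count is then the
    size of the intersection of the four TF sets minus the quadruplet's own
    members.  Exhaustive by default; sampled uniformly without replacement
    (seeded) when the enumeration would exceed ``max_quadruplets``.
    """
    _check_mode(net, mode)
    total = count_quadruplets(net, mode)
    sample = max_quadruplets is not None and total > max_quadruplets

    tf_sets: dict[str, frozenset[str]] = {}

    def tfs_of(seed: str) -> frozenset[str]:
        if seed not in tf_sets:
            tf_sets[seed] = frozenset(build_seed_subnetwork(net, seed).tfs)
        return tf_sets[seed]

    def k_of(quad: tuple[str, ...]) -> int:
        inter = tfs_of(quad[0]) & tfs_of(quad[1]) & tfs_of(quad[2]) & tfs_of(quad[3])
        return len(inter - set(quad))

    counts: dict[int, int] = {}
    if not sample:
        for quad in enumerate_quadruplets(net, mode):
            k = k_of(quad)
            counts[k] = counts.get(k, 0) + 1
        return NullDistribution(mode=mode, counts=counts, total=total, sampled=False)

    if rng_seed is None:
        raise ValidationError("rng_seed is required when sampling quadruplets")
    rng = np.random.default_rng(rng_seed)
    nodes = sorted(net.nodes)
    tfs = sorted(net.tfs)
    non_tfs = sorted(net.non_tfs)
    for idx in _sample_indices(total, max_quadruplets, rng):
        quad = _quadruplet_at(int(idx), mode, nodes, tfs, non_tfs)
        k = k_of(quad)
        counts[k] = counts.get(k, 0) + 1
    return NullDistribution(
        mode=mode, counts=counts, total=max_quadruplets, sampled=True, rng_seed=rng_seed
    )


def tail_probability(dist: NullDistribution, k_obs: int) -> float:
    """P(K >= k_obs) under the empirical null (1.0 at k_obs = 0)."""
    if k_obs < 0:
        raise ValidationError("k_obs must be >= 0")
    hits = sum(c for k, c in dist.counts.items() if k >= k_obs)
    return hits / dist.total
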