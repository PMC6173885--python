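"""Master-regulator ranking by summed directed shortest-path distance.

Every TF of the general network is a candidate regulator; its distance to
each gene of interest is the unweighted directed shortest-path length
(regulation flows along edge direction).  A TF lacking a directed path to
any one of the targets is excluded from the summed ranking — the sum is
defined only over fully connected TFs — and reported with its partial
distances instead.  Ties share a rank and are listed alphabetically.

For circuit reporting, shortest paths between genes of interest and circuit
TFs are also traced on the undirected projection (regulatory influence may
be exerted through shared regulators, not only downstream cascades); when
several shortest paths exist the lexicographically smallest node sequence
is returned together with the count of alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import RegulatoryNetwork, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DistanceTable:
    """TF x target directed distances; NaN marks an unreachable target.

    ``distances`` is indexed by TF with one column per target (ordered as
    requested).  A row's sum is defined only when every entry is finite.
    """

    distances: pd.DataFrame
    targets: tuple[str, ...]

    def sums(self) -> pd.Series:
        """Summed distance per fully connected TF (others omitted)."""
        complete = self.distances.dropna()
        return complete.sum(axis=1)


@dataclass(frozen=True)
class PathTrace:
    """One shortest undirected path between a gene of interest and a circuit TF."""

    source: str
    sink: str
    path: Optional[tuple[str, ...]]  # None when disconnected
    n_alternatives: int = 0

    @property
    def reachable(self) -> bool:
        return self.path is not None

    @property
    def length(self) -> Optional[int]:
        return None if self.path is None else len(self.path) - 1

    @property
    def n_intermediates(self) -> Optional[int]:
        return None if self.path is None else max(len(self.path) - 2, 0)


def directed_distances(
    net: RegulatoryNetwork,
    targets: Sequence[str],
    sources: Optional[Sequence[str]] = None,
) -> DistanceTable:
    """BFS shortest directed path lengths from each TF to each target.

    ``sources`` defaults to every TF of the network.  d(v, v) = 0 by the
    usual convention (relevant when a TF is itself a gene of interest);
    :func:`rank_tfs` can exclude such rows.
    """
    for t in targets:
        if t not in net:
            raise ValidationError(f"target {t!r} is not a node of the network")
    if sources is None:
        sources = sorted(net.tfs)
    g = net.to_digraph()
    rows = {}
    for s in sources:
        lengths = nx.single_source_shortest_path_length(g, s)
        rows[s] = [float(lengths[t]) if t in lengths else np.nan for t in targets]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(targets))
    table = table.sort_index()
    return DistanceTable(distances=table, targets=tuple(targets))


def rank_tfs(dist: DistanceTable, exclude_self_targets: bool = False) -> pd.DataFrame:
    """Rank fully connected TFs by ascending summed distance.

    Returns a DataFrame with the per-target distances, ``sum`` and ``rank``
    columns, sorted by (sum, TF name).  Ties share a rank (competition
    ranking); rows for TFs that cannot reach every target are dropped.
    With ``exclude_self_targets`` a TF that is itself one of the targets is
    dropped from the ranking altogether.
    """
    if not len(dist.distances):
        raise ValidationError("empty distance table")
    table = dist.distances.dropna().copy()
    if exclude_self_targets:
        table = table.loc[[t for t in table.index if t not in dist.targets]]
    if not len(table):
        logger.warning("rank_tfs: no TF reaches every target; empty ranking")
        return table.assign(sum=pd.Series(dtype=float), rank=pd.Series(dtype=int))
    table["sum"] = table[list(dist.targets)].sum(axis=1)
    # stable sort: alphabetical within equal sums
    table = table.sort_index().sort_values("sum", kind="mergesort")
    sums = table["sum"].to_numpy()
    ranks = np.empty(len(sums), dtype=int)
    for i, s in enumerate(sums):
        ranks[i] = 1 + int((sums < s).sum())
    table["rank"] = ranks
    return table


def trace_undirected_paths(
    net: RegulatoryNetwork,
    sources: Sequence[str],
    sinks: Sequence[str],
) -> list[PathTrace]:
    """One shortest undirected path per (source, sink) pair.

    Among equally short paths the lexicographically smallest node sequence
    is chosen, and the total number of shortest paths is reported.
    Disconnected pairs are recorded as unreachable, not raised.
    """
    for v in list(sources) + list(sinks):
        if v not in net:
            raise ValidationError(f"node {v!r} is not in the network")
    u = net.to_digraph().to_undirected(as_view=False)
    traces: list[PathTrace] = []
    for sink in sinks:
        dist = nx.single_source_shortest_path_length(u, sink)
        npaths = _count_shortest_paths(u, dist, sink)
        for source in sources:
            if source not in dist:
                traces.append(PathTrace(source=source, sink=sink, path=None))
                continue
            path = _lexicographic_shortest_path(u, dist, source)
            traces.append(
                PathTrace(
                    source=source,
                    sink=sink,
                    path=tuple(path),
                    n_alternatives=npaths[source] - 1,
                )
            )
    return traces


def _count_shortest_paths(u: nx.Graph, dist_to_sink: dict, sink: str) -> dict:
    """Number of shortest paths from each reachable node to the sink."""
    counts = {sink: 1}
    for v in sorted(dist_to_sink, key=dist_to_sink.get):
        if v == sink:
            continue
        counts[v] = sum(
            counts[w]
            for w in u.neighbors(v)
            if w in dist_to_sink and dist_to_sink[w] == dist_to_sink[v] - 1
        )
    return counts


def _lexicographic_shortest_path(u: nx.Graph, dist_to_sink: dict, source: str) -> list:
    """Greedy walk: at each step take the smallest neighbor one step closer."""
    path = [source]
    v = source
    while dist_to_sink[v] > 0:
        v = min(
            w
            for w in u.neighbors(v)
            if w in dist_to_sink and dist_to_sink[w] == dist_to_sink[v] - 1
        )
        path.append(v)
    return path
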