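"""Independent brute-force oracles used by the tests.

Everything here is implemented from first principles (plain dicts, nested
loops, direct summation) so the oracles share no code path with the package
implementation they check.
"""

from __future__ import annotations

from math import comb


def undirected_adjacency(edges):
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def bfs_ball(nodes, edges, seed, radius):
    """All nodes within undirected distance <= radius of the seed."""
    adj = undirected_adjacency(edges)
    for n in nodes:
        adj.setdefault(n, set())
    dist = {seed: 0}
    frontier = [seed]
    d = 0
    while frontier and d < radius:
        d += 1
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt
    return set(dist)


def prune_two_step(nodes, edges, is_tf, seed, radius=2):
    """Literal application of the stated recipe: two-level ball, one degree
    pass (everyone, seed included), then non-TF removal sparing the seed."""
    ball = bfs_ball(nodes, edges, seed, radius)
    sub_edges = [(a, b) for a, b in edges if a in ball and b in ball]
    deg = {n: 0 for n in ball}
    for a, b in sub_edges:
        deg[a] += 1
        deg[b] += 1
    keep = {n for n in ball if deg[n] >= 2}
    sub_edges = [(a, b) for a, b in sub_edges if a in keep and b in keep]
    keep = {n for n in keep if is_tf[n] or n == seed}
    sub_edges = [(a, b) for a, b in sub_edges if a in keep and b in keep]
    return keep, sub_edges


def subnetwork_tfs(nodes, edges, is_tf, seed):
    keep, _ = prune_two_step(nodes, edges, is_tf, seed)
    return {n for n in keep if is_tf[n]}


def shared_k(nodes, edges, is_tf, quad):
    """Shared-TF count of a quadruplet, seeds excluded."""
    sets = [subnetwork_tfs(nodes, edges, is_tf, s) for s in quad]
    inter = sets[0] & sets[1] & sets[2] & sets[3]
    return len(inter - set(quad))


def all_pairs_directed_distances(nodes, edges):
    """Floyd-Warshall style brute force on unweighted directed edges."""
    inf = float("inf")
    dist = {a: {b: (0 if a == b else inf) for b in nodes} for a in nodes}
    for a, b in edges:
        dist[a][b] = min(dist[a][b], 1)
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik == inf:
                continue
            row_k = dist[k]
            row_i = dist[i]
            for j in nodes:
                alt = dik + row_k[j]
                if alt < row_i[j]:
                    row_i[j] = alt
    return dist


def hypergeom_upper_tail(m, k_cat, n_hit, overlap):
    """P(X >= overlap) by direct summation of the hypergeometric pmf."""
    denom = comb(m, n_hit)
    return sum(
        comb(k_cat, x) * comb(m - k_cat, n_hit - x) / denom
        for x in range(overlap, min(k_cat, n_hit) + 1)
    )


def fisher_two_sided(table):
    """Two-sided Fisher exact p by enumerating the hypergeometric support."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        return (
            comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)
        )

    p_obs = pmf(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def bh_step_up(p_values):
    """Benjamini-Hochberg adjusted values by the textbook step-up recipe."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = p_values[i] * m / rank_from_top
        running_min = min(running_min, val)
        adjusted[i] = running_min
    return adjusted
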