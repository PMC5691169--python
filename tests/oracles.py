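"""Independent brute-force reference implementations used as oracles.

These deliberately use naive nested loops and per-node BFS so they
share no code path with the library implementations they check.
"""

import math
from collections import deque

import numpy as np


def brute_dbc_count(grid, g: int, s: int) -> int:
    """Differential box count by explicit loops over blocks and pixels."""
    m = grid.shape[0]
    sp = math.ceil(s * g / m)
    sp = max(1, sp)
    total = 0
    n_blocks = math.ceil(m / s)
    for bi in range(n_blocks):
        for bj in range(n_blocks):
            gmin, gmax = None, None
            for i in range(bi * s, min((bi + 1) * s, m)):
                for j in range(bj * s, min((bj + 1) * s, m)):
                    v = int(grid[i, j])
                    gmin = v if gmin is None else min(gmin, v)
                    gmax = v if gmax is None else max(gmax, v)
            k = math.ceil(gmin / sp)
            l = math.ceil(gmax / sp)
            total += l - k + 1
    return total


def brute_binary_count(counts, s: int) -> int:
    """Occupied-block count by explicit loops."""
    m = counts.shape[0]
    total = 0
    n_blocks = math.ceil(m / s)
    for bi in range(n_blocks):
        for bj in range(n_blocks):
            occupied = False
            for i in range(bi * s, min((bi + 1) * s, m)):
                for j in range(bj * s, min((bj + 1) * s, m)):
                    if counts[i, j] > 0:
                        occupied = True
            total += occupied
    return total


def brute_clustering(adj) -> float:
    """Mean clustering by explicit neighbor-pair enumeration."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    coeffs = []
    for j in range(n):
        nbrs = [k for k in range(n) if adj[j, k]]
        deg = len(nbrs)
        if deg < 2:
            coeffs.append(0.0)
            continue
        links = 0
        for a in range(deg):
            for b in range(a + 1, deg):
                if adj[nbrs[a], nbrs[b]]:
                    links += 1
        coeffs.append(links / (deg * (deg - 1) / 2))
    return float(np.mean(coeffs))


def _bfs_distances(adj, source):
    n = adj.shape[0]
    dist = [None] * n
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u, v] and dist[v] is None:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_cpl(adj):
    """(CPL over connected pairs, unreachable-pair fraction) via BFS."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    lengths, unreachable, pairs = [], 0, 0
    for i in range(n):
        dist = _bfs_distances(adj, i)
        for j in range(i + 1, n):
            pairs += 1
            if dist[j] is None:
                unreachable += 1
            else:
                lengths.append(dist[j])
    return float(np.mean(lengths)), unreachable / pairs


def brute_global_efficiency(adj) -> float:
    """Mean 1/distance over pairs via BFS; unreachable pairs count 0."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    inv = []
    for i in range(n):
        dist = _bfs_distances(adj, i)
        for j in range(i + 1, n):
            inv.append(0.0 if dist[j] is None else 1.0 / dist[j])
    return float(np.mean(inv)) if inv else 0.0


def random_graph_adj(rng, n, p=None):
    """Random symmetric 0/1 adjacency with zero diagonal."""
    if p is None:
        p = rng.uniform(0.15, 0.7)
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1).astype(np.int8)
    return adj | adj.T
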