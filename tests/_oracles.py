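"""Independent brute-force oracles for graph metrics and exact tests.

Everything here is deliberately naive (explicit loops, breadth-first
search, exhaustive enumeration) and shares no code with the package
implementation it checks.
"""

from collections import deque
from itertools import combinations

import numpy as np


def bf_node_strength(W):
    n = W.shape[0]
    return np.array([
        sum(W[i, j] for j in range(n)) + sum(W[j, i] for j in range(n))
        for i in range(n)
    ])


def bf_density_headline(B):
    n = B.shape[0]
    L = int(B.sum())
    return 2.0 * L / (n * (n - 1))


def _bfs_dist(adj_rows, start, nodes):
    """Hop distances from start following edges u -> v in adj_rows[u]."""
    dist = {v: np.inf for v in nodes}
    dist[start] = 0
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adj_rows[u]:
            if dist[v] == np.inf:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist

def _out_edges(B, nodes):
    # entry (i, j) nonzero means edge j -> i
    return {u: [v for v in nodes if B[v, u]] for u in nodes}


def bf_global_efficiency(B):
    n = B.shape[0]
    nodes = list(range(n))
    adj = _out_edges(B, nodes)
    total = 0.0
    for i in nodes:
        dist = _bfs_dist(adj, i, nodes)
        for j in nodes:
            if j != i and np.isfinite(dist[j]) and dist[j] > 0:
                total += 1.0 / dist[j]
    return total / (n * (n - 1))


def bf_clustering_directed(B):
    n = B.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (B[i, j] + B[j, i]) * (B[i, h] + B[h, i]) * (B[j, h] + B[h, j])
        t /= 2.0
        k_tot = sum(B[i, j] + B[j, i] for j in range(n))
        recip = sum(B[i, j] * B[j, i] for j in range(n))
        denom = k_tot * (k_tot - 1) - 2 * recip
        per_node[i] = t / denom if denom > 0 else 0.0
    return per_node


def bf_local_efficiency_directed(B):
    n = B.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and (B[i, j] or B[j, i])]
        if len(nbrs) < 2:
            continue
        adj = _out_edges(B[np.ix_(nbrs, nbrs)], list(range(len(nbrs))))
        dist = {u: _bfs_dist(adj, u, list(range(len(nbrs)))) for u in range(len(nbrs))}
        num = 0.0
        for a, j in enumerate(nbrs):
            for b, h in enumerate(nbrs):
                if a == b:
                    continue
                inv_jh = 1.0 / dist[a][b] if np.isfinite(dist[a][b]) and dist[a][b] > 0 else 0.0
                inv_hj = 1.0 / dist[b][a] if np.isfinite(dist[b][a]) and dist[b][a] > 0 else 0.0
                num += (B[i, j] + B[j, i]) * (B[i, h] + B[h, i]) * (inv_jh + inv_hj)
        num /= 2.0
        k_tot = sum(B[i, j] + B[j, i] for j in range(n))
        recip = sum(B[i, j] * B[j, i] for j in range(n))
        denom = k_tot * (k_tot - 1) - 2 * recip
        per_node[i] = num / denom if denom > 0 else 0.0
    return per_node


# ---------------------------------------------------------------------------
# Exact-test enumeration oracles
# ---------------------------------------------------------------------------

def enum_wilcoxon_p(diffs):
    """Two-sided signed-rank p by explicit enumeration of all sign vectors."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for mask in range(2 ** n):
        signs = [(mask >> k) & 1 for k in range(n)]
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    tol = 1e-9
    p_le = np.mean(ws <= w_obs + tol)
    p_ge = np.mean(ws >= w_obs - tol)
    return min(1.0, 2.0 * min(p_le, p_ge))


def enum_mannwhitney_p(a, b):
    """Two-sided Mann-Whitney p by enumerating all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in combinations(range(pooled.size), n1):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))
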