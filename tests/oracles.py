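"""Independent brute-force oracles shared by the unit and acceptance suites.

These deliberately avoid the library routines the package itself uses:
ranks, power iteration, BFS path enumeration and pairwise decompositions
are coded from first principles.
"""

import itertools
from collections import deque

import numpy as np


def logistic_closed_form(t, r, k, b0):
    """B(t) = k b0 e^{rt} / (k + b0 (e^{rt} - 1))."""
    e = np.exp(r * np.asarray(t))
    return k * b0 * e / (k + b0 * (e - 1.0))


def rank_avg(x):
    """Average ranks with ties, from first principles."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of average ranks (brute force)."""
    rx, ry = rank_avg(x), rank_avg(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def eigen_oracle(adj, iters=5000):
    """Power iteration on adj + I (same eigenvectors, no bipartite
    oscillation), max-normalized."""
    n = adj.shape[0]
    shifted = adj + np.eye(n)
    v = np.ones(n)
    for _ in range(iters):
        nxt = shifted @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            return np.zeros(n)
        v = nxt / norm
    v = np.where(v < 1e-9, 0.0, v)
    return v / v.max()


def all_shortest_paths(adj, s, t):
    n = adj.shape[0]
    dist = {s: 0}
    preds = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u, v] == 0:
                continue
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                q.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    if t not in dist:
        return []
    paths = []

    def backtrack(node, acc):
        if node == s:
            paths.append([s] + acc)
            return
        for p in preds[node]:
            backtrack(p, [node] + acc)

    backtrack(t, [])
    return paths


def betweenness_oracle(adj):
    """Enumerate all shortest paths between node pairs."""
    n = adj.shape[0]
    scores = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for p in paths:
            for node in p[1:-1]:
                scores[node] += 1.0 / len(paths)
    return scores


def bfs_ecc(adj, src):
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in range(adj.shape[0]):
            if adj[u, v] != 0 and v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def diameter_oracle(adj):
    """All-pairs BFS; assumes connectivity."""
    return max(max(bfs_ecc(adj, s).values()) for s in range(adj.shape[0]))


def bray_curtis_oracle(a, b):
    num = sum(abs(x - y) for x, y in zip(a, b))
    den = sum(x + y for x, y in zip(a, b))
    return num / den
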