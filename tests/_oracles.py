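"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: explicit slicing, textbook formulas,
pure-Python breadth-first search, exhaustive enumeration of triples and
partitions.  None of it shares code with the package.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import permutations

import numpy as np


def pearson_oracle(a, b) -> float:
    """Textbook Pearson correlation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    denom = math.sqrt((am**2).sum() * (bm**2).sum())
    return float((am * bm).sum() / denom)


def lagged_oracle(x: np.ndarray, d: int) -> np.ndarray:
    """Entry (j, k): Pearson of first N-d of x_j with last N-d of x_k."""
    n, T = x.shape
    out = np.empty((n, n))
    for j in range(n):
        for k in range(n):
            out[j, k] = pearson_oracle(x[j, : T - d], x[k, d:])
    return out


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs directed hop distances by explicit BFS."""
    n = adj.shape[0]
    D = np.full((n, n), np.inf)
    succ = [[j for j in range(n) if adj[i, j] > 0] for i in range(n)]
    for s in range(n):
        D[s, s] = 0.0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in succ[u]:
                if not np.isfinite(D[s, v]):
                    D[s, v] = D[s, u] + 1
                    q.append(v)
    return D


def diameter_oracle(adj: np.ndarray) -> float:
    D = bfs_distances(adj)
    vals = [D[i, j] for i in range(len(adj)) for j in range(len(adj))
            if i != j and np.isfinite(D[i, j])]
    return max(vals) if vals else float("nan")


def degrees_oracle(adj):
    n = adj.shape[0]
    d_in = [sum(adj[j, i] for j in range(n) if j != i) for i in range(n)]
    d_out = [sum(adj[i, j] for j in range(n) if j != i) for i in range(n)]
    return np.array(d_in), np.array(d_out)


def efficiency_oracle(adj: np.ndarray):
    """(e_in, e_out, E_in, E_out, E) from BFS distances."""
    n = adj.shape[0]
    D = bfs_distances(adj)
    e_in = np.zeros(n)
    e_out = np.zeros(n)
    for i in range(n):
        if n < 2:
            continue
        e_out[i] = sum(1.0 / D[i, j] for j in range(n) if j != i and np.isfinite(D[i, j])) / (n - 1)
        e_in[i] = sum(1.0 / D[j, i] for j in range(n) if j != i and np.isfinite(D[j, i])) / (n - 1)
    return e_in, e_out, e_in.mean(), e_out.mean(), 0.5 * (e_in.mean() + e_out.mean())


def local_efficiency_oracle(adj: np.ndarray):
    """(le_in, le_out) by materializing each neighbor subgraph explicitly."""
    n = adj.shape[0]
    le_in = np.zeros(n)
    le_out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and (adj[i, j] > 0 or adj[j, i] > 0)]
        if len(nbrs) < 2:
            continue
        sub = np.array([[adj[u, v] for v in nbrs] for u in nbrs])
        e_in, e_out, *_ = efficiency_oracle(sub)
        le_in[i] = e_in.mean()
        le_out[i] = e_out.mean()
    return le_in, le_out


def clustering_oracle(adj: np.ndarray) -> np.ndarray:
    """Cycle-triangle clustering by explicit triple enumeration."""
    n = adj.shape[0]
    c = np.zeros(n)
    for i in range(n):
        cycles = 0
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) == 3 and adj[i, j] and adj[j, k] and adj[k, i]:
                    cycles += 1
        d_in = sum(1 for j in range(n) if j != i and adj[j, i])
        d_out = sum(1 for j in range(n) if j != i and adj[i, j])
        recip = sum(1 for j in range(n) if j != i and adj[i, j] and adj[j, i])
        denom = d_in * d_out - recip
        c[i] = cycles / denom if denom > 0 else 0.0
    return c


def transitivity_oracle(adj: np.ndarray) -> float:
    """T by enumerating all ordered node triples for directed 3-cycles."""
    n = adj.shape[0]
    triangles = 0  # each directed cycle triangle counted once
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i < j and i < k and j != k and adj[i, j] and adj[j, k] and adj[k, i]:
                    triangles += 1
    denom = 0.0
    for i in range(n):
        d_tot = sum(adj[j, i] + adj[i, j] for j in range(n) if j != i)
        recip = sum(1 for j in range(n) if j != i and adj[i, j] and adj[j, i])
        denom += d_tot * (d_tot - 1) - 2 * recip
    return 3 * triangles / denom if denom > 0 else 0.0


def _set_partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def directed_modularity(adj: np.ndarray, partition, gamma: float = 1.0) -> float:
    """Directed (Leicht-Newman) modularity of a given partition."""
    m = adj.sum()
    n = adj.shape[0]
    k_out = adj.sum(axis=1)
    k_in = adj.sum(axis=0)
    comm = np.empty(n, dtype=int)
    for c, members in enumerate(partition):
        for i in members:
            comm[i] = c
    q = 0.0
    for i in range(n):
        for j in range(n):
            if comm[i] == comm[j]:
                q += adj[i, j] / m - gamma * k_out[i] * k_in[j] / m**2
    return q


def max_modularity_bruteforce(adj: np.ndarray, gamma: float = 1.0):
    """Exact maximum directed modularity over all partitions (small n only)."""
    best_q, best_p = -np.inf, None
    for part in _set_partitions(range(adj.shape[0])):
        q = directed_modularity(adj, part, gamma)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def bh_stepup_oracle(pvals, q: float):
    """Literal Benjamini-Hochberg step-up: find the largest k with
    p_(k) <= k q / m and reject the k smallest p-values."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return rejected


def all_digraphs(n: int):
    """Every labelled loop-free digraph on n nodes (2^(n(n-1)) of them)."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for mask in range(1 << len(pairs)):
        a = np.zeros((n, n))
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                a[i, j] = 1.0
        yield a
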