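"""Hand-rolled brute-force oracles, independent of the package implementation.

Everything here works by exhaustive enumeration or direct evaluation of
the defining formula, and is only feasible on tiny inputs (graphs with
<= ~8 nodes, systems with <= ~5 states).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- graphs
def enumerate_simple_paths(adj: dict, s, t):
    """All simple paths s -> t in an adjacency dict {u: {v: w}}."""
    paths = []

    def walk(node, seen, path):
        if node == t:
            paths.append(list(path))
            return
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                path.append(nb)
                walk(nb, seen, path)
                path.pop()
                seen.remove(nb)

    walk(s, {s}, [s])
    return paths


def path_weight(adj: dict, path, weighted: bool):
    if weighted:
        return sum(adj[a][b] for a, b in zip(path, path[1:]))
    return len(path) - 1


def shortest_distance(adj: dict, s, t, weighted: bool = False):
    """Min path length/weight by exhaustive path enumeration (inf if none)."""
    if s == t:
        return 0.0
    ps = enumerate_simple_paths(adj, s, t)
    if not ps:
        return math.inf
    return min(path_weight(adj, p, weighted) for p in ps)


def mean_shortest_path(adj: dict, weighted: bool = False):
    """Mean over ordered reachable pairs."""
    nodes = list(adj)
    ds = [
        shortest_distance(adj, s, t, weighted)
        for s, t in itertools.permutations(nodes, 2)
    ]
    ds = [d for d in ds if math.isfinite(d)]
    return sum(ds) / len(ds)


def clustering_by_triangles(adj: dict):
    """L_i = 2 * triangles(i) / (deg (deg - 1)) by enumeration."""
    out = {}
    for i in adj:
        nbrs = list(adj[i])
        deg = len(nbrs)
        if deg < 2:
            out[i] = 0.0
            continue
        tri = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        out[i] = 2.0 * tri / (deg * (deg - 1))
    return out


def participation_by_enumeration(adj: dict):
    """Count shortest paths strictly through each node, all co-minimal paths."""
    nodes = list(adj)
    count = {u: 0 for u in nodes}
    for p, q in itertools.combinations(nodes, 2):
        paths = enumerate_simple_paths(adj, p, q)
        if not paths:
            continue
        dmin = min(len(pa) - 1 for pa in paths)
        for pa in paths:
            if len(pa) - 1 == dmin:
                for u in pa[1:-1]:
                    count[u] += 1
    return count


def communicability_betweenness_direct(A: np.ndarray):
    """Walk-based betweenness from explicit matrix exponentials.

    exp is evaluated by symmetric eigendecomposition; for each node u the
    walks through u are E - E(u) with u's row and column zeroed, and the
    sum of ratios over ordered pairs p != q != u is normalized by
    (N-1)^2 - (N-1).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]

    def sym_expm(M):
        w, V = np.linalg.eigh(M)
        return V @ np.diag(np.exp(w)) @ V.T

    E = sym_expm(A)
    out = np.zeros(n)
    norm = (n - 1) ** 2 - (n - 1)
    for u in range(n):
        Au = A.copy()
        Au[u, :] = 0.0
        Au[:, u] = 0.0
        Eu = sym_expm(Au)
        G = E - Eu
        total = 0.0
        for p in range(n):
            for q in range(n):
                if p == q or p == u or q == u:
                    continue
                if E[p, q] != 0:
                    total += G[p, q] / E[p, q]
        out[u] = total / norm
    return out


def group_closeness_direct(adj: dict, group, weighted: bool = True):
    """G(A) = |reachable V-A| / sum of min distances from the group."""
    outside = [v for v in adj if v not in set(group)]
    dists = []
    for v in outside:
        d = min(shortest_distance(adj, u, v, weighted) for u in group)
        if math.isfinite(d):
            dists.append(d)
    if not dists or sum(dists) == 0:
        return 0.0
    return len(dists) / sum(dists)


def pearson_direct(x, y):
    """Textbook Pearson formula with explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def nx_to_adj(G, weight=None):
    """networkx graph -> adjacency dict {u: {v: w}}."""
    return {u: {v: (d.get(weight, 1) if weight else 1) for v, d in G[u].items()} for u in G.nodes()}


# --------------------------------------------------------------- control
def lsq_min_energy(Astar: np.ndarray, B: np.ndarray, x0, xf, T: float = 1.0, K: int = 4000):
    """Discretized least-squares minimum control energy.

    Euler-discretizes dx/dt = A x + B u with K steps, stacks the linear
    map from the input sequence to x(T), and solves the minimum-norm
    problem min sum ||u_k||^2 h subject to reaching xf.
    """
    Astar = np.asarray(Astar, dtype=float)
    B = np.atleast_2d(np.asarray(B, dtype=float))
    n = Astar.shape[0]
    m = B.shape[1]
    h = T / K
    Ad = np.eye(n) + h * Astar
    # propagators P_k = Ad^(K-1-k)
    powers = [np.eye(n)]
    for _ in range(K - 1):
        powers.append(Ad @ powers[-1])
    M = np.hstack([powers[K - 1 - k] @ (h * B) for k in range(K)])
    v = np.asarray(xf, dtype=float) - np.linalg.matrix_power(Ad, K) @ np.asarray(x0, dtype=float)
    u, *_ = np.linalg.lstsq(M, v, rcond=None)
    return h * float(u @ u)
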