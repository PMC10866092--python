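"""Global, nodal, and meso-structure graph statistics for FOS networks.

Global: the small-world coefficient sigma = (C_avg/C_rand)/(L_avg/L_rand)
against an ensemble of degree-preserving rewirings, and the average
shortest path length.  Nodal: degree centrality, communicability
betweenness centrality (all weighted walks, via the matrix exponential),
node clustering, shortest-path participation counts.  Mesoscale: group
closeness centrality G(A) = |V-A| / sum of minimum weighted distances to
the group, and group clustering coefficients.

Unweighted (binarized) graphs are used for sigma, clustering, degree and
participation; weighted ``distance`` edges (-ln R) are used for weighted
path lengths and group closeness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .regions import RegionSet


def rewire_preserving_degrees(G: nx.Graph, rng: np.random.Generator, n_attempts: int | None = None) -> nx.Graph:
    """Degree-preserving randomization by attempted double-edge swaps.

    Performs ``n_attempts`` (default 10 x |E|) swap attempts; an attempt
    picks two edges (u, v), (x, y) and rewires to (u, x), (v, y) unless
    that would create a self-loop or duplicate edge.  Rigid graphs (e.g.
    complete graphs, stars) pass through unchanged instead of erroring.
    """
    edges = [tuple(e) for e in G.edges()]
    m = len(edges)
    if m < 2:
        return G.copy()
    if n_attempts is None:
        n_attempts = 10 * m
    edge_set = {frozenset(e) for e in edges}
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        new1, new2 = frozenset((u, x)), frozenset((v, y))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((u, v)))
        edge_set.discard(frozenset((x, y)))
        edge_set.update((new1, new2))
        edges[i] = (u, x)
        edges[j] = (v, y)
    H = nx.Graph()
    H.add_nodes_from(G.nodes())
    H.add_edges_from(edges)
    return H


def average_shortest_path(G: nx.Graph, weighted: bool = False):
    """Mean shortest-path length over reachable pairs.

    Unweighted counts edges; weighted uses the ``distance`` edge
    attribute (-ln R).  Returns ``(L_avg, per_node, n_unreachable)``
    where ``per_node`` maps each node to its mean distance to the nodes
    it can reach and ``n_unreachable`` counts ordered unreachable pairs.
    """
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    weight = "distance" if weighted else None
    if weighted:
        it = nx.all_pairs_dijkstra_path_length(G, weight=weight)
    else:
        it = nx.all_pairs_shortest_path_length(G)
    per_node: dict = {}
    total, count, unreachable = 0.0, 0, 0
    for u, dists in it:
        others = [d for v, d in dists.items() if v != u]
        unreachable += (n - 1) - len(others)
        per_node[u] = float(np.mean(others)) if others else np.nan
        total += sum(others)
        count += len(others)
    if count == 0:
        raise ValueError("no reachable pairs")
    return total / count, per_node, unreachable


@dataclass
class SigmaResult:
    """Small-world coefficient with its components and random-ensemble means."""

    sigma: float
    C_avg: float
    L_avg: float
    C_rand: float
    L_rand: float
    n_random: int
    undefined: bool = False


def small_world_sigma(G: nx.Graph, n_random: int = 100, seed: int | None = None) -> SigmaResult:
    """sigma = (C_avg/C_rand) / (L_avg/L_rand) on the binarized graph.

    The random ensemble is ``n_random`` degree-preserving rewirings of G
    (10 x |E| attempted double-edge swaps each).  If the ensemble mean
    clustering or path length is zero, sigma is undefined and flagged.
    """
    if G.number_of_edges() < 1:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(seed)
    C_avg = nx.average_clustering(G)
    L_avg, _, _ = average_shortest_path(G, weighted=False)
    Cs, Ls = [], []
    for _ in range(n_random):
        H = rewire_preserving_degrees(G, rng)
        Cs.append(nx.average_clustering(H))
        Ls.append(average_shortest_path(H, weighted=False)[0])
    C_rand = float(np.mean(Cs))
    L_rand = float(np.mean(Ls))
    if C_rand == 0 or L_rand == 0 or C_avg == 0:
        return SigmaResult(np.nan, C_avg, L_avg, C_rand, L_rand, n_random, undefined=True)
    sigma = (C_avg / C_rand) / (L_avg / L_rand)
    return SigmaResult(sigma, C_avg, L_avg, C_rand, L_rand, n_random)


def degree_centrality(G: nx.Graph) -> dict:
    """Fraction of the other nodes each node is directly connected to."""
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return {u: G.degree(u) / (n - 1) for u in G.nodes()}


def node_clustering(G: nx.Graph) -> dict:
    """Unweighted clustering coefficient 2 * triangles / (deg * (deg - 1))."""
    return nx.clustering(G)


def communicability_betweenness(G: nx.Graph) -> dict:
    """Communicability betweenness centrality (walk-based, matrix exponential).

    For node u, sums over ordered pairs (p, q), p != q != u, the fraction
    of walks from p to q that pass through u, where walk counts come from
    exp(A) and walks through u from exp(A) - exp(A with u's row and
    column zeroed); normalized by (N-1)^2 - (N-1).
    """
    vals = {u: 0.0 for u in G.nodes()}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if sub.number_of_nodes() >= 2 and sub.number_of_edges() >= 1:
            vals.update(nx.communicability_betweenness_centrality(sub))
    return vals


def shortest_path_participation(G: nx.Graph) -> dict:
    """Number of shortest paths each node lies strictly inside.

    For node u, counts every shortest path between unordered pairs
    (p, q) with p, q != u that passes through u; all co-minimal paths
    are counted (path-count accumulation, not just one witness).
    """
    nodes = list(G.nodes())
    dist: dict = {}
    npaths: dict = {}
    for s in nodes:
        d = {s: 0}
        c = {s: 1}
        queue = [s]
        while queue:
            nxt = []
            for v in queue:
                for w in G.neighbors(v):
                    if w not in d:
                        d[w] = d[v] + 1
                        c[w] = c[v]
                        nxt.append(w)
                    elif d[w] == d[v] + 1:
                        c[w] += c[v]
            queue = nxt
        dist[s] = d
        npaths[s] = c
    part = {u: 0 for u in nodes}
    for p, q in itertools.combinations(nodes, 2):
        if q not in dist[p]:
            continue
        dpq = dist[p][q]
        for u in nodes:
            if u == p or u == q:
                continue
            if u in dist[p] and q in dist[u] and dist[p][u] + dist[u][q] == dpq:
                part[u] += npaths[p][u] * npaths[u][q]
    return part


def group_closeness(G: nx.Graph, group, weight: str = "distance", harmonic: bool = False) -> float:
    """Group closeness centrality G(A) = |V-A| / sum_v dist(A, v).

    ``dist(A, v)`` is the minimum weighted shortest-path distance from
    any group member to outside node v (edges missing the weight
    attribute count 1).  Outside nodes unreachable from the group are
    excluded from both the count and the sum; ``harmonic=True`` instead
    averages 1/dist over all outside nodes (unreachable contribute 0).
    """
    group = set(group)
    if not group:
        raise ValueError("group must be nonempty")
    nodes = set(G.nodes())
    if not group <= nodes:
        raise ValueError("group contains unknown nodes")
    outside = nodes - group
    if not outside:
        raise ValueError("group must be a strict subset of the nodes")
    dists = nx.multi_source_dijkstra_path_length(G, group, weight=lambda u, v, d: d.get(weight, 1))
    if harmonic:
        return float(np.mean([1.0 / dists[v] if v in dists and dists[v] > 0 else 0.0 for v in outside]))
    reach = [dists[v] for v in outside if v in dists]
    if not reach or sum(reach) == 0:
        return 0.0
    return len(reach) / sum(reach)


def group_clustering(G: nx.Graph, group) -> float:
    """Mean unweighted clustering coefficient over the group members."""
    group = list(group)
    if not group:
        raise ValueError("group must be nonempty")
    cl = nx.clustering(G, group)
    return float(np.mean([cl[u] for u in group]))


def nodal_metrics(G: nx.Graph) -> pd.DataFrame:
    """Per-node metric table: degree centrality, communicability
    betweenness, clustering, shortest-path participation, mean path length."""
    _, per_node_L, _ = average_shortest_path(G, weighted=False)
    data = {
        "degree_centrality": degree_centrality(G),
        "communicability_betweenness": communicability_betweenness(G),
        "clustering": node_clustering(G),
        "path_participation": shortest_path_participation(G),
        "mean_path_length": per_node_L,
    }
    return pd.DataFrame(data).loc[list(G.nodes())]


def mesoscale_metrics(G: nx.Graph, regions: RegionSet) -> pd.DataFrame:
    """Group closeness and group clustering per meso-structure."""
    rows = {}
    present = set(G.nodes())
    for s in regions.structures:
        members = [r for r in regions.members(s) if r in present]
        if not members or len(members) == len(present):
            continue
        rows[s] = {
            "group_closeness": group_closeness(G, members),
            "group_clustering": group_clustering(G, members),
            "n_regions": len(members),
        }
    return pd.DataFrame(rows).T
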