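"""FOS correlation matrices and the graphs built from them.

For each experimental group, pairwise Pearson correlations between
regional percent-change values define a functional network: nodes are
brain regions and an (undirected) edge joins every pair with a positive
correlation.  Edge weight is the correlation R; edge length is the log
inverse of the correlation, ``-ln(R)``, so strongly correlated regions
(R ~ 1) sit at distance ~0 and weakly correlated ones far apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

#: distance assigned to a perfect R = 1 edge so path algorithms stay defined
MIN_DISTANCE = 1e-12


@dataclass
class CorrelationNetwork:
    """A region x region Pearson matrix with its derived graph.

    ``R`` is symmetric with unit diagonal (NaN marks undefined pairs);
    ``graph`` is populated by :func:`build_graph` with per-edge ``weight``
    (= R) and ``distance`` (= -ln R, clamped) attributes.
    """

    R: pd.DataFrame
    group: str = ""
    graph: nx.Graph | None = None
    edge_threshold: float = 0.0

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.R.columns)


def correlation_matrix(matrix: pd.DataFrame, group: str = "", min_pairs: int = 3) -> CorrelationNetwork:
    """Pearson correlations across animals with pairwise deletion.

    ``matrix`` is animals x regions.  Pairs with fewer than ``min_pairs``
    complete paired observations, and pairs involving a constant region
    vector, are set missing (NaN) and produce no edge downstream.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 animals for a correlation network")
    R = matrix.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(R.values, 1.0)
    const = matrix.std(ddof=1) == 0
    if const.any():
        warnings.warn(
            f"constant region vectors, correlations undefined: {list(matrix.columns[const])}",
            stacklevel=2,
        )
        R.loc[const, :] = np.nan
        R.loc[:, const] = np.nan
        np.fill_diagonal(R.values, 1.0)
    return CorrelationNetwork(R=R, group=group)


def build_graph(net: CorrelationNetwork, edge_threshold: float = 0.0) -> CorrelationNetwork:
    """Populate the graph: an edge wherever R exceeds ``edge_threshold``.

    Edges carry ``weight`` (the correlation) and ``distance``
    (``-ln(R)``, clamped below at ``MIN_DISTANCE`` for R at or above 1).
    Returns the same network object with ``graph`` set.
    """
    R = net.R
    G = nx.Graph()
    G.add_nodes_from(R.columns)
    cols = list(R.columns)
    vals = R.to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = vals[i, j]
            if np.isfinite(r) and r > edge_threshold:
                dist = MIN_DISTANCE if r >= 1.0 else max(-np.log(r), MIN_DISTANCE)
                G.add_edge(cols[i], cols[j], weight=float(r), distance=float(dist))
    net.graph = G
    net.edge_threshold = edge_threshold
    return net


def binarized(net: CorrelationNetwork) -> nx.Graph:
    """Unweighted view of the network graph (same nodes and edges)."""
    if net.graph is None:
        raise ValueError("call build_graph first")
    G = nx.Graph()
    G.add_nodes_from(net.graph.nodes)
    G.add_edges_from(net.graph.edges)
    return G


def group_network(matrix: pd.DataFrame, group: str = "", edge_threshold: float = 0.0) -> CorrelationNetwork:
    """Convenience: correlation matrix plus graph in one call."""
    return build_graph(correlation_matrix(matrix, group=group), edge_threshold=edge_threshold)


def bootstrap_networks(
    matrix: pd.DataFrame,
    n_boot: int,
    seed: int = 0,
    group: str = "",
    edge_threshold: float = 0.0,
) -> list[CorrelationNetwork]:
    """One correlation network per bootstrap resample of animals.

    Each replicate draws ``len(matrix)`` animals with replacement and
    builds the group network from the resampled matrix; used for sigma
    distributions across bootstrap replicates.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    nets = []
    for b in range(n_boot):
        idx = rng.integers(0, len(matrix), size=len(matrix))
        sub = matrix.iloc[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nets.append(group_network(sub, group=f"{group}#b{b}", edge_threshold=edge_threshold))
    return nets


def write_graphml(net: CorrelationNetwork, path) -> None:
    if net.graph is None:
        raise ValueError("call build_graph first")
    nx.write_graphml(net.graph, path)


def write_edge_list(net: CorrelationNetwork, path) -> None:
    if net.graph is None:
        raise ValueError("call build_graph first")
    rows = [
        {"source": u, "target": v, "weight": d["weight"], "distance": d["distance"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "distance"]).to_csv(path, index=False)
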