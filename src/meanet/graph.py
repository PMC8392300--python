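"""Functional connectivity and graph topology.

Connectivity is the pairwise Pearson correlation of spike counts binned at
25 ms (exposed), thresholded at a fixed correlation cutoff (default 0.3) into
an undirected, binarized electrode graph.  Topology metrics follow common
network-neuroscience practice: edge count, degree, nodal clustering
coefficient, hubs as nodes more than one SD above the mean degree of
connected nodes, and the rich-club coefficient normalized against
degree-preserving double-edge-swap randomizations.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import ConnectivityGraph, SpikeTrainSet, TopologySummary

DEFAULT_BIN = 0.025  # s
DEFAULT_THRESHOLD = 0.3  # Pearson r cutoff
DEFAULT_N_NULL = 100  # degree-preserving randomizations


def bin_counts(trains: SpikeTrainSet, bin_width: float = DEFAULT_BIN) -> np.ndarray:
    """Spike counts per electrode per half-open time bin [t, t + bin).

    Returns an (n_electrodes, n_bins) integer matrix whose total equals the
    total spike count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(trains.duration / bin_width))
    counts = np.zeros((trains.n_electrodes, n_bins), dtype=int)
    for e, ts in enumerate(trains.spikes):
        if ts.size:
            idx = np.minimum((ts / bin_width).astype(int), n_bins - 1)
            np.add.at(counts[e], idx, 1)
    return counts


def pearson_connectivity(counts: np.ndarray) -> ConnectivityGraph:
    """Pearson correlation matrix of binned spike counts.

    Pairs involving a zero-variance row (silent electrodes) get r = 0 by
    convention; the diagonal is set to 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a 2-D count matrix with at least two bins")
    centered = counts - counts.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    corr = centered @ centered.T
    with np.errstate(invalid="ignore", divide="ignore"):
        corr /= np.outer(norms, norms)
    corr[~np.isfinite(corr)] = 0.0
    zero = norms == 0
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return ConnectivityGraph(corr=corr)


def threshold_graph(
    graph: ConnectivityGraph,
    threshold: float = DEFAULT_THRESHOLD,
    active_mask: np.ndarray | None = None,
) -> ConnectivityGraph:
    """Binarize the correlation matrix at a fixed r cutoff.

    An edge joins distinct electrodes with ``r >= threshold``; when an
    ``active_mask`` is given only active electrodes are eligible for edges.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    adj = graph.corr >= threshold
    np.fill_diagonal(adj, False)
    if active_mask is not None:
        active_mask = np.asarray(active_mask, dtype=bool)
        adj &= np.outer(active_mask, active_mask)
    return ConnectivityGraph(corr=graph.corr, adj=adj, threshold=threshold)


def topology(graph: ConnectivityGraph) -> TopologySummary:
    """Edge count, per-node degree and nodal clustering coefficient.

    Clustering of node i is ``2 * triangles(i) / (deg(i) * (deg(i) - 1))``,
    defined as 0 for degree < 2.
    """
    if graph.adj is None:
        raise ValueError("graph has no adjacency; run threshold_graph first")
    adj = graph.adj.astype(float)
    degree = graph.adj.sum(axis=1).astype(int)
    n_edges = int(degree.sum() // 2)
    triangles = np.diag(adj @ adj @ adj) / 2.0
    denom = degree * (degree - 1)
    clustering = np.zeros(graph.n_nodes)
    ok = denom > 0
    clustering[ok] = 2.0 * triangles[ok] / denom[ok]
    summary = TopologySummary(n_edges=n_edges, degree=degree, clustering=clustering)
    summary.hubs = hub_nodes(summary)
    return summary


def hub_nodes(summary: TopologySummary) -> list[int]:
    """Hubs: nodes with degree above mean + 1 SD of connected nodes' degrees.

    The mean and (population) SD are taken over nodes with degree > 0; a
    graph with no connected nodes, or where no node exceeds the cutoff
    (e.g. any regular graph), has no hubs.
    """
    degree = np.asarray(summary.degree)
    connected = degree > 0
    if not connected.any():
        return []
    cutoff = degree[connected].mean() + degree[connected].std()
    return [int(i) for i in np.flatnonzero(degree > cutoff)]


@dataclass(frozen=True)
class RichClubPoint:
    """Rich-club coefficient at one degree level k."""

    phi: float
    phi_null_mean: float
    phi_norm: float


def _phi(adj: np.ndarray, degree: np.ndarray, k: int) -> float | None:
    nodes = degree > k
    n = int(nodes.sum())
    if n < 2:
        return None
    e = adj[np.ix_(nodes, nodes)].sum() / 2.0
    return 2.0 * e / (n * (n - 1))


def null_adjacencies(adj: np.ndarray, n_null: int, seed: int | None = None):
    """Yield degree-preserving randomizations of a boolean adjacency matrix.

    Each replicate applies 10 x E double-edge swaps; graphs whose swap space
    is exhausted (e.g. complete graphs) are yielded as-is, their degree
    sequence being preserved either way.
    """
    adj = np.asarray(adj, dtype=bool)
    g = nx.from_numpy_array(adj)
    n_edges = g.number_of_edges()
    rng = np.random.default_rng(seed)
    for _ in range(n_null):
        h = g.copy()
        if n_edges >= 2:
            try:
                nx.double_edge_swap(
                    h,
                    nswap=10 * n_edges,
                    max_tries=100 * n_edges + 100,
                    seed=int(rng.integers(2**31)),
                )
            except nx.NetworkXAlgorithmError:
                pass
        yield nx.to_numpy_array(h, nodelist=range(adj.shape[0])) > 0


def rich_club(
    graph: ConnectivityGraph,
    n_null: int = DEFAULT_N_NULL,
    seed: int | None = None,
) -> dict[int, RichClubPoint]:
    """Normalized rich-club coefficient per degree level.

    phi(k) is the edge density of the subgraph of nodes with degree > k,
    reported for every k with at least two such nodes.  The null distribution
    comes from ``n_null`` degree-preserving double-edge-swap randomizations
    (10 x E attempted swaps each); phi_norm = phi / mean(phi_null).
    """
    if graph.adj is None:
        raise ValueError("graph has no adjacency; run threshold_graph first")
    if n_null < 1:
        raise ValueError("n_null must be at least 1")
    adj = graph.adj
    degree = adj.sum(axis=1).astype(int)
    max_deg = int(degree.max(initial=0))
    ks = [k for k in range(max_deg) if int((degree > k).sum()) >= 2]
    if not ks:
        return {}

    phis = {k: _phi(adj, degree, k) for k in ks}
    null_sums = {k: 0.0 for k in ks}
    for null_adj in null_adjacencies(adj, n_null, seed):
        for k in ks:
            null_sums[k] += _phi(null_adj, degree, k)
    out: dict[int, RichClubPoint] = {}
    for k in ks:
        null_mean = null_sums[k] / n_null
        norm = phis[k] / null_mean if null_mean > 0 else float("nan")
        out[k] = RichClubPoint(phi=phis[k], phi_null_mean=null_mean, phi_norm=norm)
    return out


def connectivity_pipeline(
    trains: SpikeTrainSet,
    bin_width: float = DEFAULT_BIN,
    threshold: float = DEFAULT_THRESHOLD,
    active_mask: np.ndarray | None = None,
) -> tuple[ConnectivityGraph, TopologySummary]:
    """Bin, correlate, threshold and summarize in one call."""
    g = pearson_connectivity(bin_counts(trains, bin_width))
    g = threshold_graph(g, threshold, active_mask)
    return g, topology(g)
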