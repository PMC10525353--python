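"""Global topological metrics of a weighted connectome.

Conventions (configurable where noted):

* connectivity strength — node level: sum of incident edge weights; network
  level: the *mean* node strength (the scale of the values reported for
  whole-brain structural networks, ~4–6 for normalized streamline weights).
* clustering coefficient — Onnela geometric-mean-of-triangle-weights form
  with weights scaled by the network maximum; network value is the mean over
  nodes, nodes of degree < 2 contributing 0.
* efficiency — edge length is 1/w (stronger connections are shorter);
  global efficiency averages inverse shortest-path length over ordered node
  pairs, unreachable pairs contributing 0; local efficiency is the mean
  over nodes of the global efficiency of the node's neighborhood subgraph
  (the node itself removed), degree < 2 nodes contributing 0.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .io import WeightedConnectome

__all__ = [
    "GlobalMetrics",
    "node_strength",
    "global_connectivity_strength",
    "clustering_coefficient",
    "global_efficiency",
    "local_efficiency",
    "compute_global_metrics",
]


@dataclasses.dataclass(frozen=True)
class GlobalMetrics:
    connectivity_strength: float
    clustering_coefficient: float
    global_efficiency: float
    local_efficiency: float


def node_strength(c: WeightedConnectome) -> np.ndarray:
    """Per-node strength: strength(i) = sum_j w(i, j)."""
    return c.weights.sum(axis=1)


def global_connectivity_strength(c: WeightedConnectome) -> float:
    """Network-level connectivity strength = mean node strength."""
    if c.n_nodes == 0:
        return 0.0
    return float(node_strength(c).mean())


def clustering_coefficient(c: WeightedConnectome) -> float:
    """Mean Onnela weighted clustering coefficient (weights / max weight)."""
    w = c.weights
    if w.size == 0 or w.max() == 0:
        return 0.0
    g = nx.from_numpy_array(w)
    cc = nx.clustering(g, weight="weight")  # Onnela form, max-normalized
    return float(np.mean(list(cc.values())))


def _efficiency_from_lengths(lengths: np.ndarray) -> float:
    """Average inverse shortest-path length over ordered pairs of a length
    (1/w) matrix; unreachable pairs contribute 0."""
    n = lengths.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _length_matrix(w: np.ndarray) -> np.ndarray:
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    return lengths


def global_efficiency(c: WeightedConnectome) -> float:
    """E_glob = (1/(n(n-1))) sum_{i != j} 1/d(i, j) with length 1/w."""
    return _efficiency_from_lengths(_length_matrix(c.weights))


def local_efficiency(c: WeightedConnectome) -> float:
    """Mean neighborhood-subgraph efficiency; degree < 2 nodes contribute 0."""
    w = c.weights
    n = c.n_nodes
    if n == 0:
        return 0.0
    lengths = _length_matrix(w)
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        vals[i] = _efficiency_from_lengths(lengths[np.ix_(nbrs, nbrs)])
    return float(vals.mean())


def compute_global_metrics(c: WeightedConnectome) -> GlobalMetrics:
    return GlobalMetrics(
        connectivity_strength=global_connectivity_strength(c),
        clustering_coefficient=clustering_coefficient(c),
        global_efficiency=global_efficiency(c),
        local_efficiency=local_efficiency(c),
    )
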