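"""The four averaged topological parameters of a thresholded network.

S — average connection strength: mean |R| over retained edges (weighted).
D — average degree: mean per-node edge count, 2|E|/n (binary).
L — average shortest path length in hops over connected pairs; unreachable
    pairs are excluded from the average, and L is undefined (NaN, flagged)
    when no pair is connected (binary).
C — average local clustering coefficient; nodes of degree < 2 contribute 0
    (binary).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import FCMatrix, ThresholdedNetwork


@dataclass
class GraphMetrics:
    S: float
    D: float
    L: float  # NaN when no pair is connected
    C: float
    n_edges: int
    no_edges: bool
    l_defined: bool
    band: str | None = None
    period: str | None = None
    alpha: float | None = None


def _check_shapes(network: ThresholdedNetwork, fc: FCMatrix) -> None:
    if network.adjacency.shape != fc.R.shape:
        raise ValueError(
            f"network shape {network.adjacency.shape} does not match "
            f"FC matrix shape {fc.R.shape}"
        )
    if network.K != fc.K:
        raise ValueError("network and FC matrix disagree on K")


def _graph(network: ThresholdedNetwork) -> nx.Graph:
    return nx.from_numpy_array(np.asarray(network.adjacency, dtype=int))


def strength(network: ThresholdedNetwork, fc: FCMatrix) -> float:
    """Mean |R| over retained edges; 0 when the edge set is empty."""
    _check_shapes(network, fc)
    iu = np.triu_indices(network.n_channels, 1)
    mask = network.adjacency[iu]
    if not mask.any():
        return 0.0
    return float(np.abs(fc.R[iu][mask]).mean())


def degree(network: ThresholdedNetwork) -> float:
    """Mean per-node edge count = 2|E|/n."""
    n = network.n_channels
    return float(2.0 * network.n_edges / n)


def path_length(network: ThresholdedNetwork) -> float:
    """Hop-count shortest paths averaged over connected (unordered) pairs.

    Unreachable pairs are excluded; returns NaN when no pair is connected.
    """
    G = _graph(network)
    total = 0.0
    n_pairs = 0
    for comp in nx.connected_components(G):
        s = len(comp)
        if s < 2:
            continue
        sub = G.subgraph(comp)
        total += nx.average_shortest_path_length(sub) * s * (s - 1) / 2.0
        n_pairs += s * (s - 1) // 2
    if n_pairs == 0:
        return float("nan")
    return total / n_pairs


def clustering(network: ThresholdedNetwork) -> float:
    """Mean local clustering coefficient; degree-<2 nodes contribute 0."""
    return float(nx.average_clustering(_graph(network)))


def graph_metrics(
    network: ThresholdedNetwork, fc: FCMatrix
) -> GraphMetrics:
    """Bundle S, D, L, C (with provenance) for one thresholded network."""
    _check_shapes(network, fc)
    L = path_length(network)
    return GraphMetrics(
        S=strength(network, fc),
        D=degree(network),
        L=L,
        C=clustering(network),
        n_edges=network.n_edges,
        no_edges=network.n_edges == 0,
        l_defined=not np.isnan(L),
        band=network.band.name if network.band is not None else None,
        period=network.period,
        alpha=network.alpha,
    )
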