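"""Connectivity graphs from partial correlations, and their metrics.

Per frequency band the epochs are band-pass filtered, one partial
correlation matrix is estimated from the concatenated clean epochs, its
absolute value becomes an undirected weighted adjacency, and a binary
graph is obtained by proportional thresholding (keep the strongest edges
up to a fixed density).  Graph summaries are node degree, mean shortest
path length over connected pairs, and transitivity.

Covariance is estimated with Ledoit-Wolf shrinkage before inversion:
with 32 channels and a limited number of clean samples the raw inverse
is unstable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import signal as sps
from sklearn.covariance import LedoitWolf

from .containers import EpochSet
from .spectral import BandDefinition, classifier_bands


def partial_correlation(
    signals: np.ndarray, shrinkage: str | float | None = "ledoit-wolf"
) -> np.ndarray:
    """Partial correlation between rows of a [channels x samples] matrix.

    pcorr_ij = -P_ij / sqrt(P_ii * P_jj) with P the inverse of the
    (shrinkage-regularized) covariance; symmetric, diagonal zeroed,
    entries in [-1, 1].
    """
    X = np.asarray(signals, dtype=float)
    if X.ndim != 2:
        raise ValueError("signals must be [channels x samples]")
    n_ch, n_s = X.shape
    if n_s <= 3:
        raise ValueError("need more than 3 samples")
    if np.ptp(X, axis=1).min() == 0:
        raise ValueError("constant channel present")
    if shrinkage == "ledoit-wolf":
        cov = LedoitWolf(assume_centered=False).fit(X.T).covariance_
    elif shrinkage is None:
        cov = np.cov(X)
    else:
        cov = np.cov(X)
        cov = (1 - float(shrinkage)) * cov + float(shrinkage) * np.trace(cov) / n_ch * np.eye(n_ch)
    try:
        P = np.linalg.inv(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular covariance; enable shrinkage or add samples"
        ) from err
    d = np.sqrt(np.abs(np.diag(P)))
    pcorr = -P / np.outer(d, d)
    pcorr = (pcorr + pcorr.T) / 2
    np.fill_diagonal(pcorr, 0.0)
    return np.clip(pcorr, -1.0, 1.0)


@dataclass
class AdjacencyMatrix:
    """Undirected weighted adjacency |pcorr| with zero diagonal."""

    W: np.ndarray
    band: BandDefinition | None = None
    meta: dict = field(default_factory=dict)


def to_adjacency(
    pcorr: np.ndarray, band: BandDefinition | None = None, **meta
) -> AdjacencyMatrix:
    """Absolute value of a partial-correlation matrix, diagonal zeroed."""
    pcorr = np.asarray(pcorr, dtype=float)
    if not np.allclose(pcorr, pcorr.T, atol=1e-8):
        raise ValueError("input matrix must be symmetric")
    W = np.abs(pcorr)
    np.fill_diagonal(W, 0.0)
    return AdjacencyMatrix(W=W, band=band, meta=meta)


def threshold_graph(adj: AdjacencyMatrix | np.ndarray, density: float = 0.2) -> nx.Graph:
    """Keep the top ceil(density * n(n-1)/2) edges by weight.

    Ties are broken by (i, j) lexicographic order.  A degenerate tie regime
    (e.g. an all-zero weight matrix) is flagged in ``G.graph['degenerate']``.
    """
    W = adj.W if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, dtype=float)
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = W.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = math.ceil(density * len(pairs))
    order = sorted(pairs, key=lambda p: (-W[p[0], p[1]], p[0], p[1]))
    kept = order[:m]
    cut_w = W[kept[-1][0], kept[-1][1]] if kept else 0.0
    n_at_cut = sum(1 for i, j in pairs if W[i, j] == cut_w)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(kept)
    G.graph["density"] = density
    G.graph["degenerate"] = bool(n_at_cut > 1 and m < len(pairs))
    return G


def node_degree(G: nx.Graph) -> np.ndarray:
    """Number of links per node, in node order."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return np.array([G.degree(v) for v in sorted(G.nodes)])


def path_length(G: nx.Graph) -> tuple[float, int]:
    """Mean shortest-path hop count over connected unordered pairs.

    Returns (mean, n_disconnected_pairs); disconnected pairs are excluded
    from the mean and counted.  A graph with no connected pair yields nan.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    total, n_pairs = 0, 0
    nodes = sorted(G.nodes)
    lengths = dict(nx.all_pairs_shortest_path_length(G))
    for a in nodes:
        for b in nodes:
            if b <= a:
                continue
            if b in lengths.get(a, {}):
                total += lengths[a][b]
                n_pairs += 1
    all_pairs = len(nodes) * (len(nodes) - 1) // 2
    mean = total / n_pairs if n_pairs else float("nan")
    return mean, all_pairs - n_pairs


def clustering_coefficient(G: nx.Graph) -> float:
    """Transitivity: 3 * triangles / connected triples, in [0, 1]."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return float(nx.transitivity(G))


@dataclass
class GraphMetrics:
    degrees: np.ndarray
    path_length: float
    n_disconnected_pairs: int
    clustering: float
    density: float


def graph_metrics(G: nx.Graph) -> GraphMetrics:
    mean_pl, n_disc = path_length(G)
    return GraphMetrics(
        degrees=node_degree(G),
        path_length=mean_pl,
        n_disconnected_pairs=n_disc,
        clustering=clustering_coefficient(G),
        density=G.graph.get("density", float("nan")),
    )


def _bandpass(data: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    hi = min(band.hi, fs / 2 * 0.99)
    sos = sps.butter(4, [band.lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=1)


def band_adjacency(
    epochs: EpochSet, band: BandDefinition, shrinkage="ledoit-wolf"
) -> AdjacencyMatrix:
    """One adjacency per subject per band, from concatenated epochs."""
    data = _bandpass(epochs.concatenated(), epochs.fs, band)
    pcorr = partial_correlation(data, shrinkage=shrinkage)
    return to_adjacency(pcorr, band=band, n_samples=data.shape[1])


def network_features(
    epochs: EpochSet,
    bands: list[BandDefinition] | None = None,
    density: float = 0.2,
    shrinkage="ledoit-wolf",
) -> dict[str, float]:
    """Per band: one degree feature per channel, plus path length and
    clustering.  Names: ``net|<band>|deg|<channel>``, ``net|<band>|pathlen``,
    ``net|<band>|cc``.
    """
    if epochs.n_channels < 2:
        raise ValueError("need at least 2 channels")
    bands = bands if bands is not None else classifier_bands()
    if not bands:
        raise ValueError("need at least 1 band")
    row: dict[str, float] = {}
    for band in bands:
        adj = band_adjacency(epochs, band, shrinkage=shrinkage)
        G = threshold_graph(adj, density=density)
        metrics = graph_metrics(G)
        for ci, ch in enumerate(epochs.channel_names):
            row[f"net|{band.name}|deg|{ch}"] = float(metrics.degrees[ci])
        row[f"net|{band.name}|pathlen"] = float(metrics.path_length)
        row[f"net|{band.name}|cc"] = float(metrics.clustering)
    return row
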