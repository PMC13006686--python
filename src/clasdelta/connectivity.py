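"""Band-limited functional connectivity and graph-theoretical metrics.

Phase coupling is estimated from the analytic signal: each epoch is
zero-phase band-passed and Hilbert transformed, giving Z_i(t) per channel.
With the instantaneous cross-spectrum C_ij(t) = Z_i(t) conj(Z_j(t)) and
expectation pooled over time points and epochs,

    wPLI_ij = |E{Im(C_ij)}| / E{|Im(C_ij)|}        in [0, 1], symmetric
    dPLI_ij = E{H(phi_i - phi_j)}                   H = Heaviside, H(0) = 0.5

wPLI is insensitive to zero-lag (volume-conduction) coupling; pairs whose
imaginary cross-spectrum is identically zero are undefined and reported 0
with a flag.  dPLI > 0.5 means channel i leads channel j; the matrix is
antisymmetric about 0.5 with diagonal exactly 0.5.

wPLI matrices are thresholded into binary undirected graphs (top proportion
of off-diagonal weights) and summarized with standard network measures
(networkx): global efficiency, mean clustering, greedy-modularity Q,
small-worldness sigma against degree-preserving rewired surrogates, node
degree, and betweenness centrality (unnormalized pair counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import signal as sps

__all__ = [
    "CONNECTIVITY_BANDS",
    "ConnectivityMatrix",
    "GraphMetrics",
    "wpli",
    "dpli",
    "threshold_adjacency",
    "graph_metrics",
    "threshold_sweep",
]

#: Band table used for connectivity (alpha runs to 14 Hz here; the
#: topography table in :mod:`clasdelta.delta` uses 8-13 Hz).
CONNECTIVITY_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
}


@dataclass
class ConnectivityMatrix:
    """Channel x channel coupling estimate for one band."""

    values: np.ndarray
    kind: str  # "wpli" | "dpli"
    band: tuple[float, float]
    n_epochs: int
    undefined: np.ndarray | None = None  # bool mask of undefined pairs (wPLI)


def _analytic_epochs(
    epochs: np.ndarray, band: tuple[float, float], fs: float
) -> np.ndarray:
    """Band-pass then Hilbert each epoch; returns complex array like input."""
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 2:
        epochs = epochs[None]
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
    lo, hi = band
    n = epochs.shape[2]
    if n / fs < 2.0 / lo:
        raise ValueError(
            f"epoch of {n / fs:.2f} s too short for band {band} "
            f"(needs >= {2.0 / lo:.1f} s)"
        )
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    padlen = min(n - 1, int(10 * fs))
    filtered = sps.sosfiltfilt(sos, epochs, axis=2, padlen=padlen)
    return sps.hilbert(filtered, axis=2)


def wpli(epochs: np.ndarray, band: tuple[float, float], fs: float
         ) -> ConnectivityMatrix:
    """Weighted phase lag index over pooled time points and epochs."""
    z = _analytic_epochs(epochs, band, fs)
    n_ep, n_ch, _ = z.shape
    num = np.zeros((n_ch, n_ch))
    den = np.zeros((n_ch, n_ch))
    for e in range(n_ep):
        ze = z[e]
        # Im(C_ij(t)) for all pairs, summed over time
        im = np.einsum("it,jt->ij", ze.imag, ze.real) - np.einsum(
            "it,jt->ij", ze.real, ze.imag
        )
        num += im
        # E{|Im(C)|} needs per-time magnitudes; chunk over time to bound memory
        T = ze.shape[1]
        step = max(1, int(2**22 // max(1, n_ch * n_ch)))
        for t0 in range(0, T, step):
            blk = ze[:, t0:t0 + step]
            imt = np.imag(blk[:, None, :] * np.conj(blk[None, :, :]))
            den += np.abs(imt).sum(axis=2)
    undefined = den <= 1e-12 * max(1, np.abs(num).max())
    values = np.zeros((n_ch, n_ch))
    ok = ~undefined
    values[ok] = np.abs(num[ok]) / den[ok]
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(undefined, True)
    return ConnectivityMatrix(values=values, kind="wpli", band=tuple(band),
                              n_epochs=n_ep, undefined=undefined)


def dpli(epochs: np.ndarray, band: tuple[float, float], fs: float
         ) -> ConnectivityMatrix:
    """Directed phase lag index over pooled time points and epochs."""
    z = _analytic_epochs(epochs, band, fs)
    n_ep, n_ch, T = z.shape
    phases = np.angle(z)
    counts = np.zeros((n_ch, n_ch))
    for e in range(n_ep):
        ph = phases[e]
        step = max(1, int(2**22 // max(1, n_ch * n_ch)))
        for t0 in range(0, T, step):
            blk = ph[:, t0:t0 + step]
            dphi = blk[:, None, :] - blk[None, :, :]
            dphi = np.mod(dphi + np.pi, 2 * np.pi) - np.pi  # wrap to (-pi, pi]
            dphi[dphi == -np.pi] = np.pi
            h = np.where(dphi > 0, 1.0, np.where(dphi == 0, 0.5, 0.0))
            counts += h.sum(axis=2)
    values = counts / (n_ep * T)
    return ConnectivityMatrix(values=values, kind="dpli", band=tuple(band),
                              n_epochs=n_ep)


def threshold_adjacency(
    matrix: ConnectivityMatrix, keep_proportion: float = 0.2
) -> nx.Graph:
    """Binarize a wPLI matrix, keeping the top proportion of edges.

    Edge count is ``round(keep_proportion * n(n-1)/2)``; ties are broken by
    lexicographic (i, j) order, so the result is deterministic.
    """
    if matrix.kind != "wpli":
        raise ValueError(f"thresholding expects a wPLI matrix, got "
                         f"{matrix.kind!r}")
    if not 0 < keep_proportion <= 1:
        raise ValueError(
            f"keep_proportion must lie in (0, 1], got {keep_proportion}"
        )
    if matrix.undefined is not None and bool(
        np.all(matrix.undefined | np.eye(len(matrix.values), dtype=bool))
    ):
        raise ValueError("all pairs undefined; nothing to threshold")
    w = matrix.values
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = sorted(range(iu.size),
                   key=lambda k: (-w[iu[k], ju[k]], iu[k], ju[k]))
    n_edges = int(round(keep_proportion * n * (n - 1) / 2))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for k in order[:n_edges]:
        g.add_edge(int(iu[k]), int(ju[k]), weight=float(w[iu[k], ju[k]]))
    return g


def threshold_sweep(
    matrix: ConnectivityMatrix,
    proportions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    n_null: int = 20,
    seed: int = 0,
) -> dict[float, "GraphMetrics"]:
    """Sensitivity sweep of graph metrics across threshold proportions."""
    return {
        p: graph_metrics(threshold_adjacency(matrix, p), n_null=n_null,
                         seed=seed)
        for p in proportions
    }


@dataclass
class GraphMetrics:
    global_efficiency: float
    clustering: float
    modularity_q: float
    small_worldness_sigma: float
    degree: dict
    betweenness: dict
    communities: list


def _char_path_length(g: nx.Graph) -> float:
    """Mean shortest path over connected ordered pairs (inf-free)."""
    total, count = 0.0, 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for target, d in dists.items():
            if d > 0:
                total += d
                count += 1
    return total / count if count else np.inf


def _rewired_null(g: nx.Graph, n_null: int, seed: int
                  ) -> tuple[float, float]:
    """Mean clustering and path length of degree-preserving surrogates."""
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    n_swap = 100 * g.number_of_edges()
    for _ in range(n_null):
        h = g.copy()
        try:
            nx.double_edge_swap(h, nswap=n_swap, max_tries=n_swap * 10,
                                seed=int(rng.integers(2**31 - 1)))
        except nx.NetworkXException:
            pass  # no swappable edges (e.g. complete graph); keep partial result
        cs.append(nx.average_clustering(h))
        ls.append(_char_path_length(h))
    return float(np.mean(cs)), float(np.mean(ls))


def graph_metrics(g: nx.Graph, n_null: int = 20, seed: int = 0
                  ) -> GraphMetrics:
    """Standard summary metrics of a binary undirected graph.

    Efficiency counts disconnected pairs as 0; clustering of degree < 2
    nodes is 0; modularity comes from greedy community search;
    small-worldness sigma = (C / C_rand) / (L / L_rand) against ``n_null``
    degree-preserving rewired surrogates (about 100 double edge swaps per
    edge, seeded).  Betweenness is reported as raw (unnormalized) shortest
    -path pair counts.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if g.number_of_nodes() < 3:
        raise ValueError("graph metrics need at least 3 nodes")
    efficiency = nx.global_efficiency(g)
    clustering = nx.average_clustering(g)
    if g.number_of_edges() > 0:
        comms = [sorted(c) for c in
                 nx.algorithms.community.greedy_modularity_communities(g)]
        q = nx.algorithms.community.modularity(g, comms)
    else:
        comms = [[n] for n in sorted(g.nodes)]
        q = 0.0
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    if g.number_of_edges() > 1:
        c_rand, l_rand = _rewired_null(g, n_null, seed)
        length = _char_path_length(g)
        if c_rand > 0 and l_rand > 0 and np.isfinite(length):
            sigma = (clustering / c_rand) / (length / l_rand)
        else:
            sigma = np.nan
    else:
        sigma = np.nan
    return GraphMetrics(
        global_efficiency=float(efficiency),
        clustering=float(clustering),
        modularity_q=float(q),
        small_worldness_sigma=float(sigma),
        degree=degree,
        betweenness=betweenness,
        communities=comms,
    )
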