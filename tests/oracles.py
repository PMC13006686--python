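"""Independent oracles used by the test suite.

These deliberately re-derive results through different routes than the
package (array scans instead of a streaming state machine; matrix power /
min-plus algebra instead of networkx) so that agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import signal as sps


# --------------------------------------------------------------------------
# offline trigger oracle: vectorized re-reading of the detection conditions
# --------------------------------------------------------------------------

def offline_triggers(raw: np.ndarray, config) -> list[int]:
    """Trigger sample indices from an offline scan of the filter output.

    Applies the same causal filter chain, then finds triggers by locating
    zero-crossings and armed excursions with array operations: for each
    upward zero-crossing, the trough is the minimum of the preceding
    negative excursion (sub-sample refined); the wave qualifies if the
    excursion dips below the arming threshold and the projected
    trough-to-peak latency (twice trough-to-crossing) is inside the window;
    the trigger lands on the first subsequent sample that clears the swing
    criterion inside the latency window.  Anti-phase is the mirror image.
    """
    from clasdelta.realtime import design_filter_chain

    kernel = design_filter_chain(config).kernel
    x = sps.lfilter(kernel, 1.0, np.asarray(raw, dtype=float))
    if config.mode == "anti_phase":
        x = -x

    fs = config.fs
    lo_ms, hi_ms = config.extremum_latency_ms
    tol = config.latency_tol_ms
    prev, cur = x[:-1], x[1:]
    ups = np.flatnonzero((prev < 0) & (cur >= 0)) + 1     # index of crossing sample
    downs = np.flatnonzero((prev >= 0) & (cur < 0)) + 1

    triggers: list[int] = []
    resume = 0  # first sample index at which detection is live again
    for u in ups:
        if u < resume:
            continue
        seg_start = downs[downs < u]
        s0 = int(seg_start[-1]) if seg_start.size else 0
        seg = x[s0:u]
        if seg.size == 0 or seg.min() >= -config.arm_threshold_uv:
            continue  # never armed
        m = s0 + int(np.argmin(seg))
        t_trough, v_trough = float(m), float(x[m])
        if 1 <= m < x.size - 1:
            a, b, c = x[m - 1], x[m], x[m + 1]
            denom = a - 2 * b + c
            if denom > 0:
                delta = 0.5 * (a - c) / denom
                if abs(delta) <= 1.0:
                    t_trough = m + delta
                    v_trough = b - 0.25 * (a - c) * delta
        t_cross = (u - 1) + (0.0 - x[u - 1]) / (x[u] - x[u - 1])
        half_ms = 2.0 * (t_cross - t_trough) / fs * 1000.0
        if not (lo_ms - tol <= half_ms <= hi_ms + tol):
            continue
        nxt = downs[downs > u]
        wave_end = int(nxt[0]) if nxt.size else x.size
        for i in range(u, wave_end):
            elapsed = (i - t_trough) / fs * 1000.0
            if elapsed > hi_ms + tol:
                break
            if elapsed >= lo_ms - tol and x[i] - v_trough > config.min_swing_uv:
                triggers.append(i)
                resume = wave_end  # suspended until next zero-crossing
                break
    return triggers


# --------------------------------------------------------------------------
# brute-force graph oracles (numpy only)
# --------------------------------------------------------------------------

def distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by repeated min-plus relaxation."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for _ in range(int(np.ceil(np.log2(max(n, 2))))):
        d = np.minimum(d, (d[:, :, None] + d[None, :, :]).min(axis=1))
    return d


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def mean_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    coeffs = []
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        k = nbrs.size
        if k < 2:
            coeffs.append(0.0)
            continue
        links = adj[np.ix_(nbrs, nbrs)].sum() / 2
        coeffs.append(links / (k * (k - 1) / 2))
    return float(np.mean(coeffs))


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness over unordered pairs via path counting.

    The number of shortest s-t paths equals the (s, t) entry of A^d(s,t);
    paths through v factor as sigma(s,v) * sigma(v,t) when distances add.
    """
    n = adj.shape[0]
    d = distances(adj)
    max_d = int(d[np.isfinite(d)].max()) if np.isfinite(d).any() else 0
    powers = [np.eye(n)]
    for _ in range(max_d):
        powers.append(powers[-1] @ adj)

    def sigma(i, j):
        dij = d[i, j]
        return powers[int(dij)][i, j] if np.isfinite(dij) else 0.0

    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]):
            continue
        st = sigma(s, t)
        for v in range(n):
            if v in (s, t):
                continue
            if d[s, v] + d[v, t] == d[s, t]:
                bc[v] += sigma(s, v) * sigma(v, t) / st
    return bc


def modularity(adj: np.ndarray, partition: list[list[int]]) -> float:
    m = adj.sum() / 2
    if m == 0:
        return 0.0
    deg = adj.sum(axis=1)
    q = 0.0
    for comm in partition:
        idx = np.array(comm)
        q += adj[np.ix_(idx, idx)].sum() / (2 * m)
        q -= (deg[idx].sum() / (2 * m)) ** 2
    return float(q)


def _partitions(items: list[int]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def max_modularity(adj: np.ndarray) -> float:
    """Exhaustive maximum modularity over all partitions (small n only)."""
    n = adj.shape[0]
    return max(modularity(adj, p) for p in _partitions(list(range(n))))


def all_graphs(n: int):
    """Yield adjacency matrices of every labeled simple graph on n nodes."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        adj = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            if bits >> k & 1:
                adj[i, j] = adj[j, i] = 1.0
        yield adj
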