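"""EEG microstate analysis: GFP peaks, polarity-invariant k-means,
back-fitting, and temporal statistics.

Microstates are quasi-stable scalp topographies.  Template maps are learned
from the topographies at global-field-power (GFP) peaks with a modified
k-means that ignores polarity (similarity = squared spatial correlation of
average-referenced maps), then the continuous recording is back-fitted by
labelling every sample with its best-matching template.  Classes are
numbered and ordered by global explained variance (GEV); no attempt is made
to identify them with the canonical A-D topographies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import Recording

__all__ = [
    "MicrostateModel",
    "MicrostateStats",
    "gfp",
    "gfp_peaks",
    "fit_microstates",
    "backfit",
    "microstate_stats",
]


def _demean(maps: np.ndarray) -> np.ndarray:
    """Average-reference maps (subtract per-map channel mean)."""
    return maps - maps.mean(axis=-2, keepdims=True)


def gfp(data: np.ndarray) -> np.ndarray:
    """Global field power: across-channel standard deviation per sample."""
    return np.asarray(data, dtype=float).std(axis=0)


def gfp_peaks(recording: Recording, min_distance_ms: float = 10.0
              ) -> np.ndarray:
    """Sample indices of local GFP maxima separated by ``min_distance_ms``."""
    g = gfp(recording.data)
    if np.ptp(g) == 0:
        return np.array([], dtype=int)
    distance = max(1, int(round(min_distance_ms * recording.fs / 1000.0)))
    peaks, _ = sps.find_peaks(g, distance=distance)
    return peaks


@dataclass
class MicrostateModel:
    """k template topographies (unit norm, channels x k) plus fit quality."""

    templates: np.ndarray
    gev: float
    k: int
    seed: int
    degenerate: bool = False
    channel_labels: list[str] | None = None


def _assign(maps: np.ndarray, templates: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Polarity-invariant assignment: argmax squared projection.

    ``maps``: (n_maps, n_channels) average-referenced; ``templates``:
    (k, n_channels) unit-norm.  Returns labels and the signed projection of
    each map on its template.
    """
    proj = maps @ templates.T  # (n_maps, k)
    labels = np.argmax(proj**2, axis=1)
    # break exact ties toward the lowest class index (argmax already does)
    signed = proj[np.arange(len(maps)), labels]
    return labels, signed


def fit_microstates(
    maps: np.ndarray,
    k: int = 4,
    n_init: int = 20,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MicrostateModel:
    """Modified (polarity-ignoring) k-means over topographic maps.

    ``maps`` has shape (n_maps, n_channels), typically topographies at GFP
    peaks.  The best of ``n_init`` seeded restarts by global explained
    variance is returned; identical seeds give identical models.  Runs that
    leave a cluster empty (e.g. identical input maps) are flagged
    degenerate.
    """
    maps = _demean(np.asarray(maps, dtype=float))
    n_maps, n_ch = maps.shape
    if n_maps < k:
        raise ValueError(f"need at least k={k} maps, got {n_maps}")
    norms = np.linalg.norm(maps, axis=1)
    total_var = float(np.sum(norms**2))
    rng = np.random.default_rng(seed)

    best_templates, best_gev, degenerate = None, -np.inf, False
    for _ in range(n_init):
        idx = rng.choice(n_maps, size=k, replace=False)
        templates = maps[idx].copy()
        tn = np.linalg.norm(templates, axis=1)
        tn[tn == 0] = 1.0
        templates /= tn[:, None]
        prev_gev = -np.inf
        for _ in range(max_iter):
            labels, signed = _assign(maps, templates)
            run_degenerate = False
            for c in range(k):
                member = labels == c
                if not member.any():
                    run_degenerate = True
                    continue
                # principal topography of the cluster, polarity-invariant:
                # dominant eigenvector of the member covariance
                m = maps[member]
                cov = m.T @ m
                vals, vecs = np.linalg.eigh(cov)
                templates[c] = vecs[:, -1]
            gev_now = float(np.sum(signed**2)) / total_var if total_var else 0.0
            if abs(gev_now - prev_gev) < tol:
                break
            prev_gev = gev_now
        labels, signed = _assign(maps, templates)
        gev_final = float(np.sum(signed**2)) / total_var if total_var else 0.0
        if gev_final > best_gev:
            best_gev = gev_final
            best_templates = templates.copy()
            degenerate = run_degenerate
    # order classes by explained variance share, descending
    labels, signed = _assign(maps, best_templates)
    shares = np.array([
        np.sum(signed[labels == c] ** 2) for c in range(k)
    ])
    order = np.argsort(-shares)
    return MicrostateModel(
        templates=best_templates[order].T,  # channels x k
        gev=best_gev,
        k=k,
        seed=seed,
        degenerate=degenerate,
    )


def backfit(model: MicrostateModel, recording: Recording) -> np.ndarray:
    """Label every sample with its best template (no temporal smoothing).

    Similarity is squared spatial correlation of the average-referenced
    topography with each template; exact ties go to the lowest class index.
    """
    if recording.n_channels != model.templates.shape[0]:
        raise ValueError(
            f"model has {model.templates.shape[0]} channels but recording "
            f"has {recording.n_channels}"
        )
    maps = _demean(recording.data.T)
    labels, _ = _assign(maps, model.templates.T)
    return labels


@dataclass
class MicrostateStats:
    mean_duration_s: dict[int, float]
    occurrence_per_s: dict[int, float]
    coverage: dict[int, float]
    transition_matrix: np.ndarray | None  # k x k row-stochastic, or None
    single_run: bool = False


def microstate_stats(labels: np.ndarray, fs: float, k: int | None = None
                     ) -> MicrostateStats:
    """Temporal statistics of a back-fitted label sequence.

    Runs of identical labels define segments.  Mean duration is the mean
    run length per class (seconds), occurrence the number of runs per
    second, coverage the fraction of samples per class; transitions are
    counted between consecutive distinct runs and row-normalized.  A
    single-run sequence has an undefined transition matrix (None, flagged).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    if k is None:
        k = int(labels.max()) + 1
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [labels.size]])
    run_labels = labels[starts]
    run_lengths = ends - starts

    total_s = labels.size / fs
    mean_duration, occurrence, coverage = {}, {}, {}
    for c in range(k):
        member = run_labels == c
        n_runs = int(member.sum())
        occurrence[c] = n_runs / total_s
        coverage[c] = float(run_lengths[member].sum()) / labels.size
        mean_duration[c] = (
            float(run_lengths[member].mean()) / fs if n_runs else 0.0
        )

    if run_labels.size < 2:
        warnings.warn("single run: transition matrix undefined", stacklevel=2)
        return MicrostateStats(mean_duration, occurrence, coverage,
                               transition_matrix=None, single_run=True)
    trans = np.zeros((k, k))
    for a, b in zip(run_labels[:-1], run_labels[1:]):
        trans[a, b] += 1
    row_sums = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(row_sums > 0, trans / row_sums, 0.0)
    return MicrostateStats(mean_duration, occurrence, coverage,
                           transition_matrix=trans)
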