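"""Microstate template derivation.

Templates are representative scalp topographies. They are derived from maps
taken at peaks of the global field power (GFP) — moments of high topographic
signal-to-noise — clustered with a polarity-invariant "modified K-means":
assignment by maximal squared spatial correlation, centroid update by the
dominant eigenvector of the assigned maps' scatter matrix. A base set of k
unsigned maps can then be polarity-expanded to 2k signed templates
(A+ ... E+, A- ... E-) by appending the exact negation of each map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .data_model import EpochSet, Montage, TemplateSet, _normalize_maps

__all__ = [
    "ClusterRun",
    "gfp",
    "gfp_series",
    "gfp_peaks",
    "modified_kmeans",
    "expand_polarity",
    "average_centroids",
]


@dataclass
class ClusterRun:
    """Settings and outcome of one modified K-means clustering run.

    tol is the convergence tolerance on the change in explained variance;
    explained_variance is filled in by :func:`modified_kmeans`.
    """

    k: int
    restarts: int = 20
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    explained_variance: float | None = None


def gfp(map_: np.ndarray) -> float:
    """Global field power: spatial standard deviation of one scalp map.

    ``sqrt(mean((v - mean(v))**2))`` over channels; zero iff the map is
    constant across channels.
    """
    v = np.asarray(map_, dtype=float)
    if v.shape[-1] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def gfp_series(data: np.ndarray) -> np.ndarray:
    """Per-sample GFP of a (channels x samples) array."""
    d = np.asarray(data, dtype=float)
    return np.sqrt(np.mean((d - d.mean(axis=0, keepdims=True)) ** 2, axis=0))


def gfp_peaks(
    data: EpochSet | np.ndarray,
    min_dist_ms: float = 10.0,
    n_per_subject: int = 2500,
    seed: int = 0,
    sfreq: float | None = None,
) -> np.ndarray:
    """Extract scalp maps at GFP peaks.

    Peaks are strict local maxima of the GFP time series separated by at
    least ``min_dist_ms``. If more than ``n_per_subject`` qualify, a seeded
    uniform random subset of that size is returned; if fewer, all are
    returned with a warning. Epoched input is concatenated along time.

    Returns an array (n_peaks, n_channels) of average-referenced maps.
    """
    if min_dist_ms <= 0:
        raise ValueError("min_dist_ms must be positive")
    if isinstance(data, EpochSet):
        sfreq = data.sfreq
        arr = np.concatenate(list(data.data), axis=1)  # channels x (trials*samples)
    else:
        if sfreq is None:
            raise ValueError("sfreq is required for raw array input")
        arr = np.asarray(data, dtype=float)
    g = gfp_series(arr)
    distance = max(1, int(round(min_dist_ms * sfreq / 1000.0)))
    peaks, _ = find_peaks(g, distance=distance)
    if peaks.size == 0:
        raise ValueError("no local maxima found in the GFP series")
    if peaks.size > n_per_subject:
        rng = np.random.default_rng(seed)
        peaks = np.sort(rng.choice(peaks, size=n_per_subject, replace=False))
    else:
        warnings.warn(
            f"only {peaks.size} GFP peaks available (requested {n_per_subject})",
            stacklevel=2,
        )
    maps = arr[:, peaks].T
    return maps - maps.mean(axis=1, keepdims=True)


def _explained_variance(normed: np.ndarray, centroids: np.ndarray,
                        assign: np.ndarray) -> float:
    """Mean over maps of squared correlation with the assigned centroid."""
    r = np.einsum("ij,ij->i", normed, centroids[assign])
    return float(np.mean(r ** 2))


def modified_kmeans(
    maps: np.ndarray,
    run: ClusterRun,
    montage: Montage | None = None,
    names: tuple[str, ...] | None = None,
) -> TemplateSet:
    """Polarity-invariant clustering of scalp maps into k base templates.

    Maps are assigned to the centroid with maximal squared spatial
    correlation (so a map and its negation always co-cluster); each centroid
    is updated to the dominant eigenvector of its members' scatter matrix.
    Iteration stops when the explained variance changes by less than
    ``run.tol`` or after ``run.max_iter`` sweeps; the best of ``run.restarts``
    seeded initializations (k maps sampled without replacement) is kept.

    Returned maps are zero-mean, unit-norm, sign-fixed so that the channel
    with the largest absolute loading is positive. ``run.explained_variance``
    is set to the winning run's final value.
    """
    X = np.asarray(maps, dtype=float)
    if X.ndim != 2:
        raise ValueError("maps must be 2-D (maps x channels)")
    n, c = X.shape
    if run.k > n:
        raise ValueError(f"k={run.k} exceeds the number of maps ({n})")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    keep = norms > 1e-12
    Xn = Xc[keep] / norms[keep, None]
    if Xn.shape[0] < run.k:
        raise ValueError("fewer non-degenerate maps than clusters")
    if run.k > 1 and np.allclose(np.abs(Xn @ Xn[0]), 1.0, atol=1e-12):
        raise ValueError("all input maps identical up to sign; k > 1 is degenerate")

    rng = np.random.default_rng(run.seed)
    best_ev, best_centroids = -np.inf, None
    for _ in range(max(1, run.restarts)):
        idx = rng.choice(Xn.shape[0], size=run.k, replace=False)
        centroids = Xn[idx].copy()
        prev_ev = -np.inf
        for _ in range(run.max_iter):
            corr = Xn @ centroids.T
            assign = np.argmax(corr ** 2, axis=1)
            # reseed empty clusters with the currently worst-explained map
            for j in range(run.k):
                if not np.any(assign == j):
                    fit = np.max(corr ** 2, axis=1)
                    worst = int(np.argmin(fit))
                    centroids[j] = Xn[worst]
                    assign[worst] = j
            for j in range(run.k):
                members = Xn[assign == j]
                scatter = members.T @ members
                w, v = np.linalg.eigh(scatter)
                centroids[j] = v[:, -1]
            centroids -= centroids.mean(axis=1, keepdims=True)
            centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
            corr = Xn @ centroids.T
            assign = np.argmax(corr ** 2, axis=1)
            ev = _explained_variance(Xn, centroids, assign)
            if ev - prev_ev < run.tol:
                prev_ev = ev
                break
            prev_ev = ev
        if prev_ev > best_ev:
            best_ev, best_centroids = prev_ev, centroids.copy()

    # deterministic sign: largest-|loading| channel positive
    for j in range(run.k):
        peak = int(np.argmax(np.abs(best_centroids[j])))
        if best_centroids[j, peak] < 0:
            best_centroids[j] *= -1.0
    run.explained_variance = best_ev

    if montage is None:
        montage = Montage(tuple(f"ch{i + 1}" for i in range(c)))
    if names is None:
        names = tuple(chr(ord("A") + i) for i in range(run.k))
    return TemplateSet(best_centroids, names, montage, base_k=run.k)


def expand_polarity(ts: TemplateSet) -> TemplateSet:
    """Append the polarity-inverted partner of every base map.

    The returned set holds 2k signed templates; names gain "+" / "-"
    suffixes and row ``k + i`` is the exact negation of row ``i``.
    """
    if ts.polarity_expanded:
        raise ValueError("template set is already polarity-expanded")
    maps = np.concatenate([ts.maps, -ts.maps], axis=0)
    names = tuple(f"{n}+" for n in ts.names) + tuple(f"{n}-" for n in ts.names)
    return TemplateSet(maps, names, ts.montage, base_k=ts.base_k,
                       polarity_expanded=True)


def average_centroids(ts: TemplateSet, pairs: list[tuple[int, int]]) -> TemplateSet:
    """Append artificial templates made by averaging pairs of base maps.

    Each appended map is the re-normalized mean of the two indexed base maps
    (e.g. pairs [(0, 1), (3, 4)] turn 5 base maps into the 7-template
    variant with A/B and D/E averages). Indices refer to base maps only.
    """
    if ts.polarity_expanded:
        raise ValueError("average_centroids operates on base (unexpanded) sets")
    extra, extra_names = [], []
    for i, j in pairs:
        if not (0 <= i < ts.base_k and 0 <= j < ts.base_k):
            raise IndexError(f"pair ({i}, {j}) out of range for base_k={ts.base_k}")
        mean = (ts.maps[i] + ts.maps[j]) / 2.0
        mean = mean - mean.mean()
        norm = np.linalg.norm(mean)
        if norm < 1e-10:
            raise ValueError(
                f"averaging templates {ts.names[i]} and {ts.names[j]} yields a zero map"
            )
        extra.append(mean / norm)
        extra_names.append(f"{ts.names[i]}{ts.names[j]}")
    maps = np.concatenate([ts.maps, np.asarray(extra)], axis=0)
    names = ts.names + tuple(extra_names)
    return TemplateSet(maps, names, ts.montage, base_k=ts.base_k + len(pairs))
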