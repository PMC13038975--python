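"""Topographic reconstruction from label distributions, scored with DISS.

A label sequence discards everything about a window except which template
won. To quantify that loss, the trial-averaged one-hot label distribution at
each window is used as weights on the template maps; the weighted sum is a
reconstructed topography, compared to the grand-averaged EEG with the global
dissimilarity

    DISS(u, v) = || u / ||u||  -  v / ||v|| ||

the Euclidean distance between the two L2-normalized maps: 0 for identical
spatial configurations, 2 for polarity-inverted ones, scale-free in between.
Both maps are average-referenced (channel mean removed) before normalizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import EpochSet, TemplateSet, WindowSpec
from .labeling import make_windows

__all__ = ["diss", "reconstruct_topographies", "reconstruction_fidelity",
           "FidelityResult"]

_EPS = 1e-12


def diss(u: np.ndarray, v: np.ndarray) -> float:
    """Global dissimilarity between two scalp maps, in [0, 2].

    Raises if either map is zero after average reference (the measure is
    undefined there).
    """
    out = []
    for name, m in (("u", u), ("v", v)):
        m = np.asarray(m, dtype=float)
        m = m - m.mean()
        norm = np.linalg.norm(m)
        if norm < _EPS:
            raise ValueError(f"map {name!r} is zero after average reference")
        out.append(m / norm)
    return float(np.linalg.norm(out[0] - out[1]))


def reconstruct_topographies(dist: np.ndarray, ts: TemplateSet) -> np.ndarray:
    """Weighted sums of template maps, one reconstruction per window.

    ``dist`` is (n_templates x n_windows) of trial-averaged one-hot label
    weights; returns (n_windows x n_channels) with
    ``recon[w] = sum_l dist[l, w] * maps[l]``. Linear in ``dist``.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != ts.n_templates:
        raise ValueError(
            f"dist must be ({ts.n_templates} templates x windows), got {dist.shape}"
        )
    return dist.T @ ts.maps


@dataclass
class FidelityResult:
    """Per-window DISS between reconstructed and grand-averaged topographies."""

    diss: np.ndarray                 # (n_windows,), NaN where flagged
    window_starts: np.ndarray
    n_flagged: int
    class_id: str

    @property
    def mean_diss(self) -> float:
        valid = self.diss[~np.isnan(self.diss)]
        if valid.size == 0:
            raise ValueError("every window was flagged; no mean DISS")
        return float(valid.mean())


def reconstruction_fidelity(
    es: EpochSet,
    dists: dict[str, np.ndarray],
    ts: TemplateSet,
    window: WindowSpec,
) -> dict[str, FidelityResult]:
    """DISS time series between reconstructions and grand-averaged EEG.

    For each class, the grand-average window-mean topography across that
    class's trials is compared to the reconstruction from ``dists[class]``
    (a templates x windows label distribution, e.g. from
    :func:`~polarstates.sequence_stats.occurrence_frequency`). Windows whose
    grand-average map is zero (cancellation) are flagged NaN and excluded
    from the mean, with the count reported.
    """
    windows = make_windows(window)
    starts = np.array([w[0] for w in windows])
    out = {}
    for cls, dist in dists.items():
        idx = np.nonzero(es.classes.astype(str) == cls)[0]
        if idx.size == 0:
            raise ValueError(f"no trials of class {cls!r}")
        recon = reconstruct_topographies(dist, ts)
        if recon.shape[0] != len(windows):
            raise ValueError("distribution windows do not match the window spec")
        values = np.full(len(windows), np.nan)
        flagged = 0
        for w, (s, e) in enumerate(windows):
            i0 = int(round((s - es.tmin) * es.sfreq))
            i1 = int(round((e - es.tmin) * es.sfreq))
            grand = es.data[idx, :, i0:i1].mean(axis=(0, 2))
            grand = grand - grand.mean()
            rmap = recon[w] - recon[w].mean()
            if np.linalg.norm(grand) < 1e-9 or np.linalg.norm(rmap) < 1e-9:
                flagged += 1
                continue
            values[w] = diss(rmap, grand)
        out[cls] = FidelityResult(values, starts, flagged, cls)
    return out
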