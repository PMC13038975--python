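"""Winner-take-all microstate labeling of epoched EEG.

Each epoch is reduced to a sequence of integer labels: the channel-wise mean
topography of every sliding window is correlated (Pearson, across channels)
with every template, and the best-matching template wins. With polarity
considered, the argmax runs over the SIGNED correlations against the 2k
signed templates, so a map and its negation receive distinct labels; with
polarity ignored, the argmax runs over ABSOLUTE correlations against the k
base maps.

Integer coding: labels index the template set directly — for an expanded set
built from base maps A..E, 0-4 are A+..E+ and 5-9 their "-" partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    SENTINEL,
    EpochSet,
    LabelSequence,
    TemplateSet,
    WindowSpec,
)

__all__ = [
    "LabelingConfig",
    "make_windows",
    "window_mean_map",
    "label_map",
    "label_epochs",
    "balance_trials",
]

_EPS = 1e-12


@dataclass(frozen=True)
class LabelingConfig:
    """How epochs are turned into label sequences.

    polarity : label against the 2k signed templates (True) or the k base
        maps by absolute correlation (False).
    tie_break : "lowest_index" — on exact correlation ties the lowest
        template index wins (the only rule implemented; deterministic).
    degenerate_policy : what to do with a zero-variance window map, for
        which Pearson correlation is undefined. "ffill" (default) repeats
        the previous window's label, leaving a leading sentinel (-1) if the
        first window is degenerate; "sentinel" keeps -1 everywhere.
    """

    window: WindowSpec
    polarity: bool = True
    tie_break: str = "lowest_index"
    degenerate_policy: str = "ffill"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tie_break not in ("lowest_index",):
            raise ValueError(f"unknown tie_break rule {self.tie_break!r}")
        if self.degenerate_policy not in ("ffill", "sentinel"):
            raise ValueError(f"unknown degenerate_policy {self.degenerate_policy!r}")


def make_windows(spec: WindowSpec) -> list[tuple[float, float]]:
    """All half-open windows ``[s, s + length)`` on the spec's grid.

    Starts run from ``t_start`` in steps of ``step`` while the window still
    fits inside ``[t_start, t_end]``.
    """
    n = int(np.floor((spec.t_end - spec.t_start - spec.length) / spec.step + 1e-9)) + 1
    starts = spec.t_start + spec.step * np.arange(n)
    return [(float(s), float(s + spec.length)) for s in starts]


def window_mean_map(
    trial: np.ndarray, window: tuple[float, float], sfreq: float, tmin: float
) -> np.ndarray:
    """Channel-wise mean of one trial over a half-open time window.

    ``trial`` is (channels x samples); the window ``(start, end)`` is in
    seconds and maps to samples via ``round((t - tmin) * sfreq)``.
    """
    i0 = int(round((window[0] - tmin) * sfreq))
    i1 = int(round((window[1] - tmin) * sfreq))
    if not (0 <= i0 < i1 <= trial.shape[1]):
        raise ValueError(f"window {window} outside the epoch or empty")
    return trial[:, i0:i1].mean(axis=1)


def _signed_correlations(maps: np.ndarray, ts: TemplateSet) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each row map against every template.

    Returns (corr, norms): corr is (n_maps, n_templates) with rows of
    degenerate (zero-variance) maps set to 0, norms the per-map L2 norms
    after channel-mean subtraction.
    """
    m = np.atleast_2d(np.asarray(maps, dtype=float))
    m = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1)
    safe = np.where(norms > _EPS, norms, 1.0)
    # templates are zero-mean unit-norm, so the dot product IS Pearson r
    corr = (m / safe[:, None]) @ ts.maps.T
    corr[norms <= _EPS] = 0.0
    return corr, norms


def label_map(
    map_: np.ndarray, ts: TemplateSet, cfg: LabelingConfig
) -> tuple[int, float]:
    """Winner-take-all label for a single topography.

    Returns ``(label, correlation)``; a degenerate (constant) map returns
    ``(SENTINEL, nan)`` for the caller's policy to resolve. Exact ties go to
    the lowest template index.
    """
    if cfg.polarity and not ts.polarity_expanded:
        raise ValueError("polarity labeling needs a polarity-expanded template set")
    if not cfg.polarity and ts.polarity_expanded:
        ts = ts.base()
    corr, norms = _signed_correlations(map_, ts)
    if norms[0] <= _EPS:
        return SENTINEL, float("nan")
    score = corr[0] if cfg.polarity else np.abs(corr[0])
    label = int(np.argmax(score))  # argmax takes the first (lowest) index on ties
    return label, float(corr[0, label])


def label_epochs(es: EpochSet, ts: TemplateSet, cfg: LabelingConfig) -> LabelSequence:
    """Transform every epoch into a one-dimensional microstate label sequence.

    Applies :func:`make_windows` -> window mean -> winner-take-all labeling
    per trial and window, vectorized across the whole epoch set.
    """
    if tuple(es.montage.channels) != tuple(ts.montage.channels):
        raise ValueError("epoch and template montages differ")
    if cfg.polarity and not ts.polarity_expanded:
        raise ValueError("polarity labeling needs a polarity-expanded template set")
    use_ts = ts if cfg.polarity else (ts.base() if ts.polarity_expanded else ts)

    windows = make_windows(cfg.window)
    starts = np.array([w[0] for w in windows])
    i0 = np.round((starts - es.tmin) * es.sfreq).astype(int)
    i1 = np.round((starts + cfg.window.length - es.tmin) * es.sfreq).astype(int)
    if i0.min() < 0 or i1.max() > es.n_samples or np.any(i0 >= i1):
        raise ValueError("window grid extends outside the epoch")

    # window means for all trials/windows at once via cumulative sums
    cs = np.concatenate(
        [np.zeros_like(es.data[..., :1]), np.cumsum(es.data, axis=2)], axis=2
    )
    means = (cs[:, :, i1] - cs[:, :, i0]) / (i1 - i0)  # trials x channels x windows
    means = np.moveaxis(means, 2, 1)  # trials x windows x channels

    n_t, n_w, n_c = means.shape
    corr, norms = _signed_correlations(means.reshape(-1, n_c), use_ts)
    score = corr if cfg.polarity else np.abs(corr)
    labels = np.argmax(score, axis=1).astype(int)
    labels[norms <= _EPS] = SENTINEL
    labels = labels.reshape(n_t, n_w)

    if cfg.degenerate_policy == "ffill":
        for i in range(n_t):
            row = labels[i]
            for w in range(1, n_w):
                if row[w] == SENTINEL and row[w - 1] != SENTINEL:
                    row[w] = row[w - 1]

    return LabelSequence(labels, starts, es.classes, use_ts.names)


def balance_trials(obj: EpochSet | LabelSequence, seed: int = 0):
    """Equalize class counts by subsampling the majority class.

    A uniform random subset (without replacement, seeded) of the majority
    class is kept so both classes match the minority count; trial order is
    otherwise preserved. Works on epochs or label sequences.
    """
    classes = obj.classes
    values, counts = np.unique(classes.astype(str), return_counts=True)
    if np.any(counts == 0) or len(values) < 2:
        raise ValueError("balancing needs two non-empty classes")
    if counts.min() == counts.max():
        return obj
    minority = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(classes), dtype=bool)
    for v, c in zip(values, counts):
        idx = np.nonzero(classes.astype(str) == v)[0]
        if c > minority:
            idx = np.sort(rng.choice(idx, size=minority, replace=False))
        keep[idx] = True
    return obj.subset(np.nonzero(keep)[0])
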