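"""Core domain types and file I/O for microstate analysis.

The pipeline works on four kinds of objects: a :class:`Montage` (ordered
channel names), a :class:`TemplateSet` (unit-norm, average-referenced scalp
maps, optionally expanded with their polarity-inverted partners), an
:class:`EpochSet` (trials x channels x samples of epoched EEG in microvolts),
and a :class:`LabelSequence` (one integer microstate label per trial per
analysis window).

File formats are deliberately plain: templates and label sequences are TSV,
epochs are an HDF5 container (with a long-format TSV fallback for tiny
hand-written fixtures).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "TemplateSet",
    "EpochSet",
    "WindowSpec",
    "LabelSequence",
    "SENTINEL",
    "average_reference",
    "read_templates",
    "write_templates",
    "read_epochs",
    "write_epochs",
    "read_labels",
    "write_labels",
]

#: Label value marking a window whose topography was degenerate (zero variance).
SENTINEL = -1

_NORM_TOL = 1e-8


@dataclass(frozen=True)
class Montage:
    """Ordered EEG channel names defining the topography dimensionality."""

    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        if len(self.channels) < 2:
            raise ValueError("a montage needs at least 2 channels")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


#: The 32 scalp positions of the international 10-10 montage used by default.
STANDARD_32 = Montage((
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "F9", "F10",
    "FC1", "FC2", "FC5", "FC6", "Cz", "C3", "C4", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6", "Pz", "P3", "P4", "P7", "P8",
    "P9", "P10", "Oz", "O1", "O2",
))


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference each row and scale it to unit L2 norm."""
    maps = np.asarray(maps, dtype=float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms < _NORM_TOL):
        bad = np.nonzero(norms.ravel() < _NORM_TOL)[0]
        raise ValueError(
            f"template map(s) {bad.tolist()} are zero after average reference"
        )
    return maps / norms


@dataclass(frozen=True)
class TemplateSet:
    """A set of microstate template maps.

    ``maps`` has one zero-mean, unit-norm row per template. A polarity-expanded
    set holds ``2 * base_k`` rows where row ``base_k + i`` is the exact
    negation of row ``i`` and names carry ``+`` / ``-`` suffixes.
    """

    maps: np.ndarray
    names: tuple[str, ...]
    montage: Montage
    base_k: int
    polarity_expanded: bool = False

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        if maps.ndim != 2:
            raise ValueError("maps must be 2-D (templates x channels)")
        if maps.shape[1] != self.montage.n_channels:
            raise ValueError("map width does not match montage")
        names = tuple(self.names)
        if len(names) != maps.shape[0]:
            raise ValueError("one name per template required")
        if len(set(names)) != len(names):
            raise ValueError("template names must be unique")
        expected = 2 * self.base_k if self.polarity_expanded else self.base_k
        if maps.shape[0] != expected:
            raise ValueError(
                f"expected {expected} maps for base_k={self.base_k}, "
                f"polarity_expanded={self.polarity_expanded}; got {maps.shape[0]}"
            )
        if self.polarity_expanded:
            # Exact negation is an invariant, not a tolerance check.
            maps[self.base_k:] = -maps[: self.base_k]
        object.__setattr__(self, "maps", maps)
        object.__setattr__(self, "names", names)

    @property
    def n_templates(self) -> int:
        return self.maps.shape[0]

    def base(self) -> "TemplateSet":
        """The underlying base (unsigned) template set."""
        if not self.polarity_expanded:
            return self
        names = tuple(n[:-1] if n.endswith("+") else n for n in self.names[: self.base_k])
        return TemplateSet(self.maps[: self.base_k].copy(), names, self.montage, self.base_k)

    def polarity_partner(self, label: int) -> int:
        """Index of the sign-flipped partner of ``label`` in an expanded set."""
        if not self.polarity_expanded:
            raise ValueError("template set is not polarity-expanded")
        return label + self.base_k if label < self.base_k else label - self.base_k


@dataclass
class EpochSet:
    """Epoched multichannel EEG with per-trial stimulus classes.

    data : array (n_trials, n_channels, n_samples), microvolts
    sfreq : sampling rate in Hz
    tmin : epoch start in seconds relative to stimulus onset (<= 0)
    classes : per-trial category string, e.g. "standard" / "target"
    ground_truth : optional planted per-sample label track (synthetic data)
    """

    data: np.ndarray
    sfreq: float
    tmin: float
    classes: np.ndarray
    montage: Montage
    ground_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel dimension does not match montage")
        self.classes = np.asarray(self.classes, dtype=object)
        if self.classes.shape[0] != self.data.shape[0]:
            raise ValueError("one class per trial required")
        n_classes = len(set(self.classes.tolist()))
        if self.data.shape[0] and n_classes != 2:
            warnings.warn(
                f"expected exactly 2 stimulus classes, found {n_classes}",
                stacklevel=2,
            )
        tmax = self.tmin + self.data.shape[2] / self.sfreq
        if not (self.tmin <= 0.0 < tmax):
            raise ValueError("epoch must contain the stimulus onset (t=0)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def tmax(self) -> float:
        return self.tmin + self.n_samples / self.sfreq

    def sample_index(self, t: float) -> int:
        """Sample index of time ``t`` (seconds), ``round((t - tmin) * sfreq)``."""
        return int(round((t - self.tmin) * self.sfreq))

    def subset(self, idx: np.ndarray) -> "EpochSet":
        gt = None if self.ground_truth is None else self.ground_truth[idx]
        return EpochSet(self.data[idx], self.sfreq, self.tmin,
                        self.classes[idx], self.montage, gt)


@dataclass(frozen=True)
class WindowSpec:
    """A sliding-window grid: half-open windows ``[s, s + length)``.

    All fields in seconds. Windows start at ``t_start`` and advance by
    ``step`` while they fit fully inside ``[t_start, t_end]``.
    """

    t_start: float
    t_end: float
    length: float
    step: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("window length must be positive")
        if not (0 < self.step <= self.length):
            raise ValueError("step must satisfy 0 < step <= length")
        if self.t_start + self.length > self.t_end + 1e-12:
            raise ValueError("no window fits in [t_start, t_end]")

    @property
    def overlap(self) -> float:
        """Fractional overlap of consecutive windows."""
        return (self.length - self.step) / self.length


@dataclass
class LabelSequence:
    """Per-trial, per-window integer microstate labels.

    ``labels[i, w]`` is the index into ``template_names`` of the winning
    template for trial ``i`` in window ``w`` (or :data:`SENTINEL` for a
    degenerate window).
    """

    labels: np.ndarray
    window_starts: np.ndarray
    classes: np.ndarray
    template_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D (trials x windows)")
        if self.labels.shape[1] != self.window_starts.shape[0]:
            raise ValueError("one window start per label column required")
        if self.labels.shape[0] != self.classes.shape[0]:
            raise ValueError("one class per trial required")
        lo, hi = self.labels.min(initial=0), self.labels.max(initial=0)
        if lo < SENTINEL or hi >= len(self.template_names):
            raise ValueError("labels out of range for the template set")
        if self.window_starts.size > 1:
            steps = np.diff(self.window_starts)
            if not (np.all(steps > 0) and np.allclose(steps, steps[0], atol=1e-9)):
                raise ValueError("window starts must increase with constant step")

    @property
    def n_trials(self) -> int:
        return self.labels.shape[0]

    @property
    def n_windows(self) -> int:
        return self.labels.shape[1]

    def subset(self, idx: np.ndarray) -> "LabelSequence":
        return LabelSequence(self.labels[idx], self.window_starts,
                             self.classes[idx], self.template_names)


# ---------------------------------------------------------------------------
# operations


def average_reference(es: EpochSet) -> EpochSet:
    """Re-reference every sample to the mean across channels.

    Idempotent; preserves all inter-channel differences.
    """
    data = es.data - es.data.mean(axis=1, keepdims=True)
    return replace(es, data=data)


# ---------------------------------------------------------------------------
# template I/O


def read_templates(path: str | Path) -> TemplateSet:
    """Read a template TSV (header ``name<TAB>ch1..chN``, one map per row).

    Maps are re-normalized (zero channel mean, unit L2 norm) on read, with a
    warning if the stored values were not already normalized. A set whose
    second half exactly negates its first half (with ``+``/``-`` suffixed
    names) is recognized as polarity-expanded.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError("template file needs a name column and >= 2 channels")
    names = df.iloc[:, 0].astype(str).tolist()
    if len(set(names)) != len(names):
        raise ValueError("duplicate template names in file")
    raw = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(raw).any():
        raise ValueError("template row length does not match header")
    maps = _normalize_maps(raw)
    if not np.allclose(raw, maps, atol=1e-6):
        warnings.warn("template maps were re-normalized on read", stacklevel=2)
    montage = Montage(tuple(df.columns[1:]))

    k = maps.shape[0]
    expanded = (
        k % 2 == 0
        and k >= 2
        and np.allclose(maps[k // 2:], -maps[: k // 2], atol=1e-9)
        and all(n.endswith("+") for n in names[: k // 2])
        and all(n.endswith("-") for n in names[k // 2:])
    )
    if expanded:
        return TemplateSet(maps, tuple(names), montage, base_k=k // 2,
                           polarity_expanded=True)
    return TemplateSet(maps, tuple(names), montage, base_k=k)


def write_templates(ts: TemplateSet, path: str | Path) -> Path:
    """Write a template set as TSV; an expanded set writes all 2k rows."""
    path = Path(path)
    df = pd.DataFrame(ts.maps, columns=list(ts.montage.channels))
    df.insert(0, "name", list(ts.names))
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# epoch I/O


def write_epochs(es: EpochSet, path: str | Path) -> Path:
    """Write epochs to HDF5 (``.h5``/``.hdf5``) or long TSV (``.tsv``)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=es.data)
            f.create_dataset(
                "class", data=np.array([str(c) for c in es.classes], dtype="S")
            )
            if es.ground_truth is not None:
                f.create_dataset("ground_truth", data=es.ground_truth)
            f.attrs["sfreq"] = es.sfreq
            f.attrs["tmin"] = es.tmin
            f.attrs["channels"] = [str(c) for c in es.montage.channels]
        return path
    if path.suffix == ".tsv":
        n_t, n_c, n_s = es.data.shape
        t, c, s = np.meshgrid(range(n_t), range(n_c), range(n_s), indexing="ij")
        pd.DataFrame({
            "trial": t.ravel(), "channel": c.ravel(), "sample": s.ravel(),
            "value": es.data.ravel(),
        }).to_csv(path, sep="\t", index=False)
        meta = {
            "sfreq": es.sfreq, "tmin": es.tmin,
            "channels": list(es.montage.channels),
            "classes": [str(c) for c in es.classes],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        return path
    raise ValueError(f"unsupported epoch container suffix: {path.suffix!r}")


def read_epochs(path: str | Path) -> EpochSet:
    """Read epochs written by :func:`write_epochs` (lossless round trip)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise ValueError("epoch container lacks the 'data' dataset")
            for attr in ("sfreq", "tmin", "channels"):
                if attr not in f.attrs:
                    raise ValueError(f"epoch container lacks the {attr!r} attribute")
            data = f["data"][()]
            classes = np.array([c.decode() for c in f["class"][()]], dtype=object)
            gt = f["ground_truth"][()] if "ground_truth" in f else None
            montage = Montage(tuple(str(c) for c in f.attrs["channels"]))
            return EpochSet(data, float(f.attrs["sfreq"]), float(f.attrs["tmin"]),
                            classes, montage, gt)
    if path.suffix == ".tsv":
        meta = json.loads(path.with_suffix(".json").read_text())
        for attr in ("sfreq", "tmin", "channels", "classes"):
            if attr not in meta:
                raise ValueError(f"epoch sidecar lacks the {attr!r} attribute")
        df = pd.read_csv(path, sep="\t")
        n_t = int(df["trial"].max()) + 1
        n_c = int(df["channel"].max()) + 1
        n_s = int(df["sample"].max()) + 1
        data = np.zeros((n_t, n_c, n_s))
        data[df["trial"], df["channel"], df["sample"]] = df["value"]
        return EpochSet(data, float(meta["sfreq"]), float(meta["tmin"]),
                        np.array(meta["classes"], dtype=object),
                        Montage(tuple(meta["channels"])))
    raise ValueError(f"unsupported epoch container suffix: {path.suffix!r}")


# ---------------------------------------------------------------------------
# label-sequence I/O


def write_labels(seq: LabelSequence, path: str | Path) -> Path:
    """Write a label sequence as TSV (header = window starts in ms) + JSON sidecar."""
    path = Path(path)
    cols = [f"{1000.0 * t:g}" for t in seq.window_starts]
    pd.DataFrame(seq.labels, columns=cols).to_csv(path, sep="\t", index=False)
    sidecar = {
        "template_names": list(seq.template_names),
        "classes": [str(c) for c in seq.classes],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_labels(path: str | Path) -> LabelSequence:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    starts = np.array([float(c) for c in df.columns]) / 1000.0
    return LabelSequence(df.to_numpy(dtype=int), starts,
                         np.array(sidecar["classes"], dtype=object),
                         tuple(sidecar["template_names"]))
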