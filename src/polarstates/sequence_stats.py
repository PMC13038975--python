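"""Occurrence-frequency maps and cluster-corrected label statistics.

Occurrence frequency of a label in a window is the fraction of trials
carrying that label there; computed per stimulus class it gives the familiar
label-by-time occupancy heatmaps. Class differences are tested per label
with a one-sample t across participants at every window, cluster-corrected
by permutation (max-cluster-mass null from participant-level sign flips),
with Benjamini-Hochberg FDR across the clusters pooled over labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .data_model import SENTINEL, LabelSequence

__all__ = [
    "FrequencyMap",
    "Cluster",
    "ClusterResult",
    "occurrence_frequency",
    "frequency_difference",
    "time_resolved_onehot",
    "permutation_cluster_test",
    "fdr_across_labels",
    "label_cluster_analysis",
    "split_by_prediction",
]


@dataclass
class FrequencyMap:
    """Per-label, per-window occurrence probabilities for one class."""

    freq: np.ndarray                 # (n_templates, n_windows), values in [0, 1]
    window_starts: np.ndarray
    class_id: str
    n_trials: int


@dataclass
class Cluster:
    """A maximal run of supra-threshold windows for one label."""

    label: int
    start: int                       # window indices, inclusive
    end: int
    mass: float                      # sum of |t| over the run
    p: float
    q: float | None = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    alpha: float
    seed: int
    excluded_windows: dict[int, list[int]] = field(default_factory=dict)


def occurrence_frequency(
    seq: LabelSequence, by_class: bool = True
) -> dict[str, FrequencyMap]:
    """Fraction of trials carrying each label, per window (and per class).

    Sentinel labels are excluded from the counts, so columns sum to 1 only
    for sentinel-free data. With ``by_class=False`` a single map keyed
    ``"all"`` pools every trial.
    """
    if seq.n_trials == 0:
        raise ValueError("empty label sequence")
    n_l = len(seq.template_names)
    groups: dict[str, np.ndarray]
    if by_class:
        groups = {
            str(v): np.nonzero(seq.classes.astype(str) == v)[0]
            for v in np.unique(seq.classes.astype(str))
        }
    else:
        groups = {"all": np.arange(seq.n_trials)}
    out = {}
    for cls, idx in groups.items():
        labels = seq.labels[idx]
        freq = np.stack([(labels == l).mean(axis=0) for l in range(n_l)])
        out[cls] = FrequencyMap(freq, seq.window_starts, cls, len(idx))
    return out


def frequency_difference(
    fm_target: FrequencyMap, fm_standard: FrequencyMap
) -> np.ndarray:
    """Target-minus-standard occurrence difference, elementwise."""
    if fm_target.freq.shape != fm_standard.freq.shape:
        raise ValueError("frequency maps have mismatched shapes")
    return fm_target.freq - fm_standard.freq


def time_resolved_onehot(seq: LabelSequence) -> dict[str, np.ndarray]:
    """Trial-averaged one-hot label time courses, per class.

    For one participant this equals the occurrence frequency; sentinel
    windows simply contribute zero to every label's indicator.
    """
    return {cls: fm.freq for cls, fm in occurrence_frequency(seq).items()}


def _clusters_from_t(t: np.ndarray, thresh: float) -> list[tuple[int, int, float]]:
    """Maximal runs where |t| exceeds ``thresh``; returns (start, end, mass)."""
    supra = np.abs(t) > thresh
    lab, n = ndimage.label(supra)
    out = []
    for j in range(1, n + 1):
        idx = np.nonzero(lab == j)[0]
        out.append((int(idx[0]), int(idx[-1]), float(np.abs(t[idx]).sum())))
    return out


def _t_1samp(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t per column with an explicit zero-variance validity mask."""
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    valid = sd > 1e-12 * (1.0 + np.abs(mean))
    t = np.zeros_like(mean)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    return t, valid


def _t_rows(flipped_sums: np.ndarray, sq_sums: np.ndarray, n: int) -> np.ndarray:
    """One-sample t per window for each row of sign-flipped column sums.

    Uses the identity that the per-participant sum of squares is invariant
    under sign flips, so only the flipped sums vary across permutations.
    """
    mean = flipped_sums / n
    var = (sq_sums - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


def permutation_cluster_test(
    diffs: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    seed: int = 0,
    scheme: str = "sign_flip",
    label: int = 0,
) -> tuple[list[Cluster], list[int]]:
    """Cluster-corrected one-sample permutation test on one label's differences.

    ``diffs`` is (participants x windows), e.g. per-participant target-minus-
    standard occurrence time courses. Pointwise one-sample t-statistics are
    thresholded two-sided at ``alpha_cluster``; clusters are maximal
    supra-threshold runs scored by summed |t|, compared against the maximum
    cluster mass over ``n_perm`` permutations. The default null flips the
    sign of whole participant time-series ("sign_flip"); "circular_shift"
    instead circularly shifts each participant's series in time. P-values
    carry the (1 + exceedances) / (1 + n_perm) correction; note that under
    sign flips a draw flipping every participant reproduces |t| exactly, so
    even a noise-free effect cannot fall below
    (1 + #sign-symmetric draws) / (1 + n_perm).

    Windows where t is undefined (zero variance across participants) are
    excluded and reported in the second return value. Participant rows are
    sorted canonically before the null is drawn, so results do not depend on
    participant ordering.
    """
    X = np.asarray(diffs, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("diffs must be (>=2 participants) x windows")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if scheme not in ("sign_flip", "circular_shift"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    # canonical participant order: null draws become order-invariant
    X = X[np.lexsort(X.T[::-1])]
    n, w = X.shape

    t_obs, valid = _t_1samp(X)
    excluded = np.nonzero(~valid)[0].tolist()
    thresh = stats.t.ppf(1.0 - alpha_cluster / 2.0, df=n - 1)
    observed = _clusters_from_t(np.where(valid, t_obs, 0.0), thresh)
    if not observed:
        return [], excluded

    rng = np.random.default_rng(seed)
    if scheme == "sign_flip":
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        flipped_sums = signs @ X               # (n_perm, windows)
        sq_sums = (X ** 2).sum(axis=0)
        t_null = _t_rows(flipped_sums, sq_sums, n)
    else:
        t_null = np.empty((n_perm, w))
        for p in range(n_perm):
            shifts = rng.integers(0, w, size=n)
            shifted = np.stack([np.roll(X[i], shifts[i]) for i in range(n)])
            t_p, valid_p = _t_1samp(shifted)
            t_null[p] = np.where(valid_p, t_p, 0.0)
    t_null[:, ~valid] = 0.0

    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        runs = _clusters_from_t(t_null[p], thresh)
        if runs:
            null_max[p] = max(m for _, _, m in runs)

    clusters = [
        Cluster(label=label, start=s, end=e, mass=m,
                p=float((1 + np.sum(null_max >= m)) / (1 + n_perm)))
        for s, e, m in observed
    ]
    return clusters, excluded


def fdr_across_labels(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values for a pooled vector of cluster p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    return multipletests(p, method="fdr_bh")[1]


def label_cluster_analysis(
    per_label_diffs: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    seed: int = 0,
    scheme: str = "sign_flip",
    fdr_pool: str = "across_labels",
) -> ClusterResult:
    """Run the cluster test for every label and FDR-correct across labels.

    ``per_label_diffs`` is (n_labels x participants x windows). By default
    all clusters are pooled for a single BH pass ("across_labels"); with
    ``fdr_pool="per_label"`` BH runs within each label separately.
    """
    if fdr_pool not in ("across_labels", "per_label"):
        raise ValueError(f"unknown fdr_pool {fdr_pool!r}")
    all_clusters: list[Cluster] = []
    excluded: dict[int, list[int]] = {}
    for l in range(per_label_diffs.shape[0]):
        cl, ex = permutation_cluster_test(
            per_label_diffs[l], n_perm=n_perm, alpha_cluster=alpha_cluster,
            seed=seed + l, scheme=scheme, label=l,
        )
        all_clusters.extend(cl)
        if ex:
            excluded[l] = ex
    if all_clusters:
        if fdr_pool == "across_labels":
            q = fdr_across_labels([c.p for c in all_clusters])
            for c, qv in zip(all_clusters, q):
                c.q = float(qv)
        else:
            for l in {c.label for c in all_clusters}:
                group = [c for c in all_clusters if c.label == l]
                q = fdr_across_labels([c.p for c in group])
                for c, qv in zip(group, q):
                    c.q = float(qv)
    return ClusterResult(all_clusters, n_perm, alpha_cluster, seed, excluded)


def split_by_prediction(
    seq: LabelSequence, predictions: np.ndarray
) -> tuple[LabelSequence, LabelSequence]:
    """Partition trials into (correctly, incorrectly) classified subsets.

    ``predictions`` holds one out-of-fold predicted class per trial; a trial
    is "correct" when its prediction matches its true class.
    """
    pred = np.asarray(predictions, dtype=object)
    if pred.shape[0] != seq.n_trials:
        raise ValueError("need exactly one prediction per trial")
    correct = pred.astype(str) == seq.classes.astype(str)
    return seq.subset(np.nonzero(correct)[0]), seq.subset(np.nonzero(~correct)[0])
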