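"""Synthetic oddball EEG sessions with planted microstate dynamics.

The study's recordings are not public, so the pipeline is exercised on
simulated sessions: each trial is a piecewise-constant sequence of signed
microstate segments (geometric durations), the segment label drawn from a
class-conditional, time-varying categorical prior. The EEG at each sample is
the signed template map scaled by an amplitude envelope, plus spatially
correlated Gaussian noise. Ground-truth per-sample label tracks are kept so
that labeling accuracy, occupancy recovery and classification effects can be
checked exactly.

The default configuration mirrors a 32-channel oddball session: 320 standard
and 80 target trials, epochs from -200 to 1000 ms at 1000 Hz, with target
trials biased toward C+/E+ in 0-200 ms, C-/D-/E- in 200-400 ms and back to
C+/E+ after 500 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import toeplitz

from .data_model import STANDARD_32, EpochSet, Montage, TemplateSet, average_reference
from .templates import expand_polarity

__all__ = [
    "PriorProfile",
    "SimConfig",
    "SimSession",
    "default_oddball_config",
    "null_oddball_config",
    "polarity_contrast_config",
    "simulate_session",
    "smooth_orthogonal_templates",
]


@dataclass(frozen=True)
class PriorProfile:
    """Piecewise-constant categorical prior over signed labels.

    ``edges`` (seconds, length n_segments + 1) partition the epoch;
    ``probs[s]`` is the label distribution in ``[edges[s], edges[s+1])``.
    """

    edges: tuple[float, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != len(self.edges) - 1:
            raise ValueError("probs must be (n_segments x n_labels)")
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each prior row must be a probability vector")
        object.__setattr__(self, "probs", probs)

    @property
    def n_labels(self) -> int:
        return self.probs.shape[1]

    def at(self, t: float) -> np.ndarray:
        """Label distribution at time ``t`` (seconds)."""
        s = int(np.searchsorted(self.edges, t, side="right")) - 1
        s = min(max(s, 0), self.probs.shape[0] - 1)
        return self.probs[s]

    @staticmethod
    def uniform(edges: tuple[float, float], n_labels: int) -> "PriorProfile":
        return PriorProfile(edges, np.full((1, n_labels), 1.0 / n_labels))


@dataclass(frozen=True)
class SimConfig:
    """Everything that determines one simulated oddball session."""

    montage: Montage
    template_set: TemplateSet            # base (unsigned) maps
    prior_standard: PriorProfile         # over the 2k signed labels
    prior_target: PriorProfile
    n_standard: int = 320
    n_target: int = 80
    sfreq: float = 1000.0
    tmin: float = -0.2
    tmax: float = 1.0
    mean_segment_ms: float = 80.0
    amplitude_uv: float = 5.0
    envelope: str = "rect_sin"           # "rect_sin" | "constant"
    envelope_freq_hz: float = 10.0
    noise_sd_uv: float = 2.0
    noise_smoothness: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template_set.polarity_expanded:
            raise ValueError("SimConfig takes the base (unexpanded) template set")
        n_signed = 2 * self.template_set.base_k
        for name, prior in (("standard", self.prior_standard),
                            ("target", self.prior_target)):
            if prior.n_labels != n_signed:
                raise ValueError(
                    f"{name} prior has {prior.n_labels} labels, expected {n_signed}"
                )
        if not self.n_standard >= self.n_target >= 1:
            raise ValueError("need n_standard >= n_target >= 1")
        if self.mean_segment_ms <= 0:
            raise ValueError("mean_segment_ms must be positive")
        if not 0.0 <= self.noise_smoothness < 1.0:
            raise ValueError("noise_smoothness must lie in [0, 1)")
        if self.envelope not in ("rect_sin", "constant"):
            raise ValueError(f"unknown envelope {self.envelope!r}")


@dataclass
class SimSession:
    """A simulated session: epochs (with ground-truth tracks) plus its config."""

    epochs: EpochSet
    config: SimConfig


def smooth_orthogonal_templates(
    base_k: int, montage: Montage, seed: int
) -> TemplateSet:
    """Random smooth scalp maps, pairwise orthogonalized.

    Gaussian channel noise is smoothed along the channel ordering, then
    Gram-Schmidt orthogonalized, average-referenced and unit-normed. These
    stand in for canonical microstate classes A-E, whose numeric values are
    not public; names follow the A, B, C ... convention.
    """
    rng = np.random.default_rng(seed)
    n_c = montage.n_channels
    raw = rng.standard_normal((base_k, n_c))
    kernel = np.exp(-0.5 * (np.arange(-3, 4) / 1.5) ** 2)
    smooth = np.array([np.convolve(r, kernel, mode="same") for r in raw])
    smooth -= smooth.mean(axis=1, keepdims=True)
    # Gram-Schmidt within the zero-mean subspace
    maps = []
    for v in smooth:
        for u in maps:
            v = v - (v @ u) * u
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise ValueError("degenerate template draw; change the seed")
        maps.append(v / norm)
    maps = np.asarray(maps)
    for j in range(base_k):
        if maps[j, np.argmax(np.abs(maps[j]))] < 0:
            maps[j] *= -1.0
    names = tuple(chr(ord("A") + i) for i in range(base_k))
    return TemplateSet(maps, names, montage, base_k=base_k)


def _boost(n_labels: int, boosted: dict[int, float]) -> np.ndarray:
    """A prior row giving fixed mass to ``boosted`` labels, the rest uniform."""
    row = np.zeros(n_labels)
    rest = 1.0 - sum(boosted.values())
    others = n_labels - len(boosted)
    row[:] = rest / others
    for idx, p in boosted.items():
        row[idx] = p
    return row


def default_oddball_config(
    seed: int,
    n_standard: int = 320,
    n_target: int = 80,
    noise_sd_uv: float = 2.0,
) -> SimConfig:
    """The reference oddball simulation.

    32 channels, 5 base templates (A-E), epochs -0.2 to 1.0 s at 1000 Hz.
    The standard-class prior is uniform over the 10 signed labels at all
    times; the target-class prior boosts C+/E+ in 0-200 ms, C-/D-/E- in
    200-400 ms, and C+/E+ again after 500 ms.
    """
    montage = STANDARD_32
    ts = smooth_orthogonal_templates(5, montage, seed)
    n_signed = 10
    c_pos, e_pos = 2, 4          # C+, E+ in A+..E+, A-..E- coding
    c_neg, d_neg, e_neg = 7, 8, 9
    tmin, tmax = -0.2, 1.0
    uniform = np.full(n_signed, 0.1)
    prior_standard = PriorProfile((tmin, tmax), uniform[None, :])
    prior_target = PriorProfile(
        (tmin, 0.0, 0.2, 0.4, 0.5, tmax),
        np.stack([
            uniform,
            _boost(n_signed, {c_pos: 0.25, e_pos: 0.25}),
            _boost(n_signed, {c_neg: 0.2, d_neg: 0.2, e_neg: 0.2}),
            uniform,
            _boost(n_signed, {c_pos: 0.25, e_pos: 0.25}),
        ]),
    )
    return SimConfig(montage=montage, template_set=ts,
                     prior_standard=prior_standard, prior_target=prior_target,
                     n_standard=n_standard, n_target=n_target,
                     noise_sd_uv=noise_sd_uv, seed=seed)


def null_oddball_config(
    seed: int, n_standard: int = 100, n_target: int = 100,
    noise_sd_uv: float = 2.0,
) -> SimConfig:
    """A no-class-effect session: both classes share the same uniform prior."""
    cfg = default_oddball_config(seed, n_standard, n_target, noise_sd_uv)
    return replace(cfg, prior_target=cfg.prior_standard)


def polarity_contrast_config(
    seed: int, n_standard: int = 40, n_target: int = 40,
    noise_sd_uv: float = 1.0,
) -> SimConfig:
    """Classes that differ ONLY by topographic polarity.

    Standard trials draw uniformly from the five "+" labels, target trials
    uniformly from the five "-" labels: polarity-ignored labeling sees the
    two classes as identical, polarity-considered labeling separates them.
    """
    cfg = default_oddball_config(seed, n_standard, n_target, noise_sd_uv)
    pos = np.zeros(10)
    pos[:5] = 0.2
    neg = np.zeros(10)
    neg[5:] = 0.2
    tmin, tmax = cfg.tmin, cfg.tmax
    return replace(
        cfg,
        prior_standard=PriorProfile((tmin, tmax), pos[None, :]),
        prior_target=PriorProfile((tmin, tmax), neg[None, :]),
    )


def _noise_mixer(n_channels: int, smoothness: float) -> np.ndarray:
    """Symmetric channel-mixing matrix with unit-L2 rows.

    Off-diagonal weight decays as smoothness**|i-j|, so ``smoothness=0`` is
    white noise and higher values give spatially correlated noise; unit rows
    keep the per-channel noise SD at the configured value.
    """
    if smoothness == 0.0:
        return np.eye(n_channels)
    m = toeplitz(smoothness ** np.arange(n_channels))
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def simulate_session(cfg: SimConfig) -> SimSession:
    """Generate one session from ``cfg``; fully reproducible given its seed.

    Segment durations are geometric at sample resolution with the configured
    mean; each segment's signed label is drawn from the class prior at the
    segment's onset time. EEG = amplitude * envelope(t) * signed map +
    spatially correlated Gaussian noise, then average-referenced.
    """
    rng = np.random.default_rng(cfg.seed)
    signed = expand_polarity(cfg.template_set)
    n_signed = signed.n_templates
    n_samples = int(round((cfg.tmax - cfg.tmin) * cfg.sfreq))
    times = cfg.tmin + np.arange(n_samples) / cfg.sfreq
    mean_samples = max(cfg.mean_segment_ms / 1000.0 * cfg.sfreq, 1.0)
    p_end = 1.0 / mean_samples

    if cfg.envelope == "rect_sin":
        env = np.abs(np.sin(2 * np.pi * cfg.envelope_freq_hz * times))
    else:
        env = np.ones(n_samples)

    n_trials = cfg.n_standard + cfg.n_target
    classes = np.array(
        ["standard"] * cfg.n_standard + ["target"] * cfg.n_target, dtype=object
    )
    mixer = _noise_mixer(cfg.montage.n_channels, cfg.noise_smoothness)

    data = np.empty((n_trials, cfg.montage.n_channels, n_samples))
    tracks = np.empty((n_trials, n_samples), dtype=int)
    for i in range(n_trials):
        prior = cfg.prior_target if classes[i] == "target" else cfg.prior_standard
        cur = 0
        while cur < n_samples:
            dur = int(rng.geometric(p_end))
            lab = int(rng.choice(n_signed, p=prior.at(times[cur])))
            tracks[i, cur:cur + dur] = lab
            cur += dur
        signal = (signed.maps[tracks[i]] * (cfg.amplitude_uv * env)[:, None]).T
        if cfg.noise_sd_uv > 0:
            noise = cfg.noise_sd_uv * (
                mixer @ rng.standard_normal((cfg.montage.n_channels, n_samples))
            )
        else:
            noise = 0.0
        data[i] = signal + noise

    epochs = EpochSet(data, cfg.sfreq, cfg.tmin, classes, cfg.montage,
                      ground_truth=tracks)
    return SimSession(epochs=average_reference(epochs), config=cfg)
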