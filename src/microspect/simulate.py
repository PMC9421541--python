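"""Synthetic two-group EEG cohorts with known microstate ground truth.

The generator emulates the phenomenology that microstate analysis rests on:
a semi-Markov sequence of quasi-stable topographic states (gamma-distributed
dwell times around 50-120 ms), each state expressed as a fixed scalp map
multiplied by a band-limited oscillatory carrier whose polarity flips at
random between segments, plus spatially correlated sensor noise. Group 2
("patients") carries a configurable deficit in one map's dwell time and
occurrence, mirroring a map-E deficit between patients and controls.

Every subject stores its true label sequence, and the true temporal measures
are computed through the same run-length code path used by backfitting, so
parameter-recovery tests compare like with like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .backfit import SegmentationResult, TemporalMeasures, compute_measures
from .core import EEGRecording
from .templates import CANONICAL_LABELS, SCHEMATIC_1020, make_canonical_templates

__all__ = ["SyntheticConfig", "GroundTruth", "simulate_subject", "simulate_cohort"]

logger = logging.getLogger(__name__)

#: Index of the map carrying the group-2 deficit (map E).
DEFICIT_MAP = 4


@dataclass
class SyntheticConfig:
    """Generative settings for a two-group cohort.

    Defaults follow the recording and cohort design the analysis targets:
    19-channel 10-20 montage at 250 Hz, 3-minute eyes-open recordings,
    61 subjects per group, ~80 ms mean dwell times, and a group-2 deficit in
    map E's duration and occurrence.
    """

    n_channels: int = 19
    sfreq: float = 250.0
    duration: float = 180.0
    templates: np.ndarray | None = None
    montage: list[str] = field(default_factory=lambda: list(SCHEMATIC_1020))
    mean_dwell: float = 80.0  # ms
    dwell_shape: float = 2.0  # gamma shape; shape 2 avoids memoryless dwell times
    carrier_bands: list[tuple[float, float]] | None = None  # per-map (low, high) Hz
    snr: float = 5.0  # state-signal RMS over noise RMS
    subject_cv: float = 0.3  # lognormal sigma of per-subject, per-map dwell/occurrence multipliers
    #: optional second, independent state process confined to another band
    #: (band-specific dynamics: the broadband signal mixes both processes,
    #: a narrow-band analysis isolates one). The group deficit applies only
    #: to the primary process.
    background_band: tuple[float, float] | None = None
    background_weight: float = 1.0
    group2_mapE_duration_scale: float = 0.6
    group2_mapE_occurrence_scale: float = 0.6
    n_per_group: int = 61
    seed: int = 0

    def __post_init__(self) -> None:
        if self.templates is None:
            self.templates = make_canonical_templates(self.n_channels, self.montage)
        self.templates = np.asarray(self.templates, dtype=float)
        if self.carrier_bands is None:
            # default: all maps share the alpha band
            self.carrier_bands = [(8.0, 12.0)] * self.n_maps
        if len(self.carrier_bands) != self.n_maps:
            raise ValueError("one carrier band per template required")
        if self.mean_dwell <= 0 or self.dwell_shape <= 0:
            raise ValueError("mean_dwell and dwell_shape must be positive")
        if not (self.snr > 0):
            raise ValueError("snr must be positive")
        if self.subject_cv < 0:
            raise ValueError("subject_cv must be nonnegative")
        for name, s in (
            ("group2_mapE_duration_scale", self.group2_mapE_duration_scale),
            ("group2_mapE_occurrence_scale", self.group2_mapE_occurrence_scale),
        ):
            if not (0 < s <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        t = self.templates
        if not np.allclose(t.mean(axis=1), 0, atol=1e-9):
            raise ValueError("templates must be average-referenced")
        if not np.allclose(np.linalg.norm(t, axis=1), 1, atol=1e-9):
            raise ValueError("templates must be unit-norm")
        C = np.abs(t @ t.T) - np.eye(self.n_maps)
        if C.max() >= 0.95:
            raise ValueError("templates are near-collinear (|r| >= 0.95)")

    @property
    def n_maps(self) -> int:
        return self.templates.shape[0]

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sfreq))


@dataclass
class GroundTruth:
    """True per-sample state sequence and the measures derived from it."""

    label_sequence: np.ndarray
    true_measures: TemporalMeasures

    def __post_init__(self) -> None:
        self.label_sequence = np.asarray(self.label_sequence, dtype=int)


def _state_sequence(
    cfg: SyntheticConfig, group: int, rng: np.random.Generator
) -> np.ndarray:
    """Semi-Markov label sequence with gamma dwell times.

    Each subject draws lognormal per-map multipliers for its mean dwell
    times and transition weights (between-subject heterogeneity); group 2
    additionally scales map E's mean dwell (duration deficit) and its
    transition weight (occurrence deficit).
    """
    k = cfg.n_maps
    mean_dwell = np.full(k, cfg.mean_dwell)
    weights = np.ones(k)
    if cfg.subject_cv > 0:
        mean_dwell = mean_dwell * rng.lognormal(0.0, cfg.subject_cv, size=k)
        weights = weights * rng.lognormal(0.0, cfg.subject_cv, size=k)
    if group == 2:
        mean_dwell[DEFICIT_MAP] *= cfg.group2_mapE_duration_scale
        weights[DEFICIT_MAP] *= cfg.group2_mapE_occurrence_scale
    n = cfg.n_samples
    labels = np.empty(n, dtype=int)
    state = int(rng.choice(k, p=weights / weights.sum()))
    t = 0
    while t < n:
        dwell_ms = rng.gamma(cfg.dwell_shape, mean_dwell[state] / cfg.dwell_shape)
        dwell = max(1, int(round(dwell_ms * cfg.sfreq / 1000.0)))
        labels[t : t + dwell] = state
        t += dwell
        w = weights.copy()
        w[state] = 0.0
        state = int(rng.choice(k, p=w / w.sum()))
    return labels


def _band_noise(
    low: float, high: float, n: int, sfreq: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (the oscillatory carrier)."""
    sos = sps.butter(4, [low, high], btype="bandpass", fs=sfreq, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * int(sfreq)))
    x = x[int(sfreq) : int(sfreq) + n]  # drop filter edge transients
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _noise_mixing(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-subject spatially correlated noise mixing matrix.

    Spatial correlation follows a squared-exponential kernel over the
    schematic electrode positions with a random per-subject length-scale,
    plus a small white component for full rank.
    """
    pos = np.array(
        [SCHEMATIC_1020.get(lbl, (0.0, 0.0)) for lbl in cfg.montage[: cfg.n_channels]]
    )
    ell = rng.uniform(0.3, 0.6)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2 * ell**2)) + 0.1 * np.eye(cfg.n_channels)
    return np.linalg.cholesky(K)


def _state_signal(
    cfg: SyntheticConfig,
    labels: np.ndarray,
    bands: list[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Channels x samples signal for one state process.

    Each map's topography is gated by its label segments and multiplied by a
    band-limited oscillatory carrier; segment polarity flips at random
    (microstates are polarity-invariant).
    """
    n = labels.size
    carriers = np.stack(
        [_band_noise(lo, hi, n, cfg.sfreq, rng) for lo, hi in bands]
    )
    seg_starts = np.concatenate(([0], np.flatnonzero(np.diff(labels)) + 1))
    signs = np.ones(n)
    for s, e in zip(seg_starts, np.concatenate((seg_starts[1:], [n]))):
        signs[s:e] = rng.choice([-1.0, 1.0])
    amp = carriers[labels, np.arange(n)] * signs
    return cfg.templates[labels].T * amp


def simulate_subject(
    cfg: SyntheticConfig, group: int, subject_seed: int
) -> tuple[EEGRecording, GroundTruth]:
    """Simulate one subject's recording; reproducible under (cfg.seed, subject_seed)."""
    if group not in (1, 2):
        raise ValueError(f"group must be 1 or 2, got {group}")
    rng = np.random.default_rng([cfg.seed, group, subject_seed])
    labels = _state_sequence(cfg, group, rng)
    n = cfg.n_samples
    signal = _state_signal(cfg, labels, cfg.carrier_bands, rng)

    if cfg.background_band is not None:
        # independent state process in another band, never carrying the
        # group deficit: broadband analysis sees the mixture of processes
        labels_bg = _state_sequence(cfg, 1, rng)
        bg_bands = [tuple(cfg.background_band)] * cfg.n_maps
        signal = signal + cfg.background_weight * _state_signal(
            cfg, labels_bg, bg_bands, rng
        )

    sig_rms = np.sqrt(np.mean(signal**2))
    if np.isfinite(cfg.snr):
        L = _noise_mixing(cfg, rng)
        noise = L @ rng.standard_normal((cfg.n_channels, n))
        noise *= sig_rms / (cfg.snr * np.sqrt(np.mean(noise**2)))
    else:
        noise = 0.0
    data = 10.0 * (signal + noise)  # arbitrary microvolt scale

    rec = EEGRecording(
        data=data,
        sfreq=cfg.sfreq,
        channel_labels=list(cfg.montage[: cfg.n_channels]),
        subject_id=f"g{group}s{subject_seed:04d}",
        group=group,
    )
    seg = SegmentationResult(
        labels=labels,
        corr=np.ones(n),
        sfreq=cfg.sfreq,
        params={"k": cfg.n_maps},
    )
    map_labels = list(CANONICAL_LABELS[: cfg.n_maps]) if cfg.n_maps <= 5 else None
    truth = GroundTruth(
        label_sequence=labels,
        true_measures=compute_measures(seg, map_labels=map_labels, n_maps=cfg.n_maps),
    )
    return rec, truth


def simulate_cohort(cfg: SyntheticConfig) -> list[tuple[EEGRecording, GroundTruth]]:
    """Simulate 2 x n_per_group subjects (all group 1, then all group 2)."""
    if cfg.n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    out = []
    for group in (1, 2):
        for i in range(cfg.n_per_group):
            out.append(simulate_subject(cfg, group, subject_seed=i))
    return out
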