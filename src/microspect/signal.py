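"""Deterministic signal layer: filtering, referencing, GFP, peaks, epoch rejection."""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .core import BandSpec, EEGRecording

__all__ = [
    "average_reference",
    "bandpass",
    "gfp",
    "extract_gfp_peaks",
    "reject_epochs_zscore",
]

logger = logging.getLogger(__name__)


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average: subtract the per-sample channel mean.

    Idempotent; after application every sample has zero channel mean.
    """
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


def bandpass(rec: EEGRecording, band: BandSpec) -> EEGRecording:
    """Zero-phase band-pass filter (4th-order Butterworth, forward-backward).

    Forward-backward application doubles the effective order and cancels the
    phase response, preserving topography timing.
    """
    nyq = rec.sfreq / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name} high cut {band.high} Hz >= Nyquist {nyq} Hz"
        )
    sos = sps.butter(4, [band.low, band.high], btype="bandpass", fs=rec.sfreq, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=data)


def gfp(rec: EEGRecording | np.ndarray) -> np.ndarray:
    """Global field power: per-sample spatial standard deviation across channels.

    Population (not sample) standard deviation, which equals the RMS of the
    average-referenced sample — the microstate-literature convention.
    """
    data = rec.data if isinstance(rec, EEGRecording) else np.asarray(rec, dtype=float)
    return data.std(axis=0, ddof=0)


def extract_gfp_peaks(
    rec: EEGRecording, max_peaks: int | None = 1000, seed: int = 0
) -> np.ndarray:
    """Indices of strict local maxima of the GFP series, subsampled to ``max_peaks``.

    A peak satisfies GFP[t-1] < GFP[t] > GFP[t+1] (interior samples only).
    When more than ``max_peaks`` peaks exist a uniformly random subset is
    drawn under ``seed``; indices are returned sorted ascending.
    """
    if rec.n_samples < 3:
        raise ValueError("need at least 3 samples to find GFP peaks")
    g = gfp(rec)
    interior = (g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size == 0:
        logger.warning("no GFP peaks found in recording %s", rec.subject_id)
        return peaks
    if max_peaks is not None and peaks.size > max_peaks:
        rng = np.random.default_rng(seed)
        peaks = np.sort(rng.choice(peaks, size=max_peaks, replace=False))
    return peaks


def reject_epochs_zscore(
    rec: EEGRecording, epoch_len: float = 1.0, z_thresh: float = 2.0
) -> tuple[EEGRecording, np.ndarray]:
    """Reject fixed-length epochs whose mean absolute amplitude is an outlier.

    The per-epoch statistic (mean absolute amplitude over channels and
    samples) is z-scored across epochs; epochs with ``|z| > z_thresh`` are
    dropped and the survivors concatenated. Returns the concatenated
    recording (with seam indices recorded wherever non-adjacent epochs now
    abut) and the boolean keep-mask.
    """
    n_ep_samples = int(round(epoch_len * rec.sfreq))
    n_epochs = rec.n_samples // n_ep_samples
    if n_epochs < 2:
        raise ValueError("recording shorter than two epochs")
    trimmed = rec.data[:, : n_epochs * n_ep_samples]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_ep_samples)
    stat = np.abs(epochs).mean(axis=(0, 2))
    sd = stat.std(ddof=0)
    z = np.zeros_like(stat) if sd == 0 else (stat - stat.mean()) / sd
    keep = np.abs(z) <= z_thresh
    if not keep.any():
        raise ValueError("all epochs rejected")
    kept_idx = np.flatnonzero(keep)
    data = epochs[:, keep, :].reshape(rec.n_channels, -1)
    # a seam occurs where consecutive retained epochs were not adjacent originally
    seams = (np.flatnonzero(np.diff(kept_idx) > 1) + 1) * n_ep_samples
    return rec.copy_with(data=data, seams=seams), keep
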