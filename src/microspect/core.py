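"""Core containers: EEG recordings and frequency-band definitions.

A recording is a plain channels x samples matrix in microvolts together with
its sampling rate and channel labels. Microstate analysis only ever needs the
average-referenced signal, so the container stays deliberately thin; readers
and writers live in :mod:`microspect.io`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["BandSpec", "DEFAULT_BANDS", "EEGRecording", "derive_seed"]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with low/high cut-offs in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band {self.name}: {self.low}-{self.high} Hz")


#: Analysis bands: broadband plus the four classical rhythms (note the 12-15 Hz
#: gap between alpha and beta is intentional and part of the band scheme).
DEFAULT_BANDS: dict[str, BandSpec] = {
    "broadband": BandSpec("broadband", 1.0, 30.0),
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 15.0, 30.0),
}

BAND_ORDER = ("broadband", "delta", "theta", "alpha", "beta")


@dataclass
class EEGRecording:
    """One subject's multichannel EEG.

    Parameters
    ----------
    data : channels x samples array, microvolts.
    sfreq : sampling rate in Hz.
    channel_labels : electrode names, one per row of ``data``.
    subject_id : free-form identifier.
    group : optional group tag (1 = control, 2 = patient).
    seams : sample indices at which concatenated epochs meet after epoch
        rejection; label runs may not span a seam.
    """

    data: np.ndarray
    sfreq: float
    channel_labels: list[str]
    subject_id: str = ""
    group: int | None = None
    seams: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or infinite values")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.group is not None and self.group not in (1, 2):
            raise ValueError(f"group must be 1 or 2, got {self.group}")
        self.seams = np.asarray(self.seams, dtype=int)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    def copy_with(self, **kwargs) -> "EEGRecording":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


def derive_seed(global_seed: int, *parts) -> int:
    """Deterministically derive a sub-seed from a global seed and a unit id.

    Stage and per-unit seeds are hashes of ``(global_seed, *parts)`` so that
    pipeline stages are reproducible independently of execution order.
    Result is a non-negative int below 2**31.
    """
    h = hashlib.sha256(repr((int(global_seed),) + tuple(parts)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
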