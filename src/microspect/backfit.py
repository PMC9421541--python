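"""Backfitting: sample-wise map assignment, smoothing, and temporal measures.

Every sample of a (band-filtered, average-referenced) recording is labeled
with the prototype map of maximal absolute spatial correlation, or left
unassigned when that correlation falls below a threshold. Labels are then
temporally smoothed with a window-count penalty, runs shorter than a minimum
duration are split between their neighbors, and per-map occurrence, mean
duration, and time coverage are computed from the final run-length encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .core import DEFAULT_BANDS, BandSpec, EEGRecording
from .clustering import MicrostateMapSet, corr_matrix
from .signal import average_reference, bandpass

__all__ = [
    "UNASSIGNED",
    "SegmentationResult",
    "TemporalMeasures",
    "assign_labels",
    "smooth_labels",
    "enforce_min_duration",
    "compute_measures",
    "band_pipeline",
]

logger = logging.getLogger(__name__)

#: Sentinel label for samples not assigned to any map.
UNASSIGNED = -1


@dataclass
class SegmentationResult:
    """Per-sample map labels (0-based; ``UNASSIGNED`` = -1) and fit correlations."""

    labels: np.ndarray
    corr: np.ndarray
    sfreq: float
    params: dict = field(default_factory=dict)
    seams: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.labels.shape != self.corr.shape:
            raise ValueError("labels and corr must have equal length")
        self.seams = np.asarray(self.seams, dtype=int)


@dataclass
class TemporalMeasures:
    """Per-map temporal statistics of a segmentation.

    occurrence : segments per second of total recording time (1/s)
    mean_duration_ms : mean length of interior (non-boundary) segments
    coverage : fraction of all samples carrying the map's label
    present : whether the map appears at all
    """

    map_labels: list[str]
    occurrence: np.ndarray
    mean_duration_ms: np.ndarray
    coverage: np.ndarray
    present: np.ndarray
    unassigned_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "map": self.map_labels,
                "occurrence_hz": self.occurrence,
                "mean_duration_ms": self.mean_duration_ms,
                "coverage": self.coverage,
                "present": self.present,
            }
        )


def assign_labels(
    rec: EEGRecording, maps: MicrostateMapSet, threshold: float = 0.50
) -> SegmentationResult:
    """Label each sample with its best-matching map by absolute spatial correlation.

    Samples whose best correlation falls below ``threshold`` — and
    zero-variance samples — are marked unassigned. Ties resolve to the
    lowest map index.
    """
    data = average_reference(rec).data
    C = corr_matrix(data.T, maps.maps)
    labels = C.argmax(axis=1)
    best = C[np.arange(C.shape[0]), labels]
    zero_var = data.std(axis=0) == 0
    unassigned = (best < threshold) | zero_var
    labels[unassigned] = UNASSIGNED
    best[zero_var] = 0.0
    return SegmentationResult(
        labels=labels,
        corr=best,
        sfreq=rec.sfreq,
        params={"assign_threshold": threshold, "k": maps.k},
        seams=rec.seams,
    )


def smooth_labels(
    seg: SegmentationResult,
    rec: EEGRecording,
    maps: MicrostateMapSet,
    window: int = 7,
    factor: float = 10.0,
) -> SegmentationResult:
    """Temporally smooth labels with a windowed label-count bonus.

    Each sample's fit score for map m is its spatial correlation plus
    ``factor / (2 * window)`` times the number of samples within +-window
    (excluding the sample itself) currently labeled m. Labels are re-chosen
    by maximal adjusted score and the procedure iterates to a fixed point
    (at most 50 sweeps). Unassigned samples are re-assigned only when their
    best adjusted score crosses the assignment threshold; zero-variance
    samples stay unassigned. ``factor = 0`` reproduces the input labels.
    """
    if factor == 0:
        return replace(seg, params={**seg.params, "smooth_window": window, "smooth_factor": factor})
    data = average_reference(rec).data
    C = corr_matrix(data.T, maps.maps)
    n, k = C.shape
    threshold = seg.params.get("assign_threshold", 0.50)
    eligible = data.std(axis=0) > 0
    labels = seg.labels.copy()
    weight = factor / (2.0 * window)
    span = 2 * window + 1
    for _ in range(50):
        onehot = np.zeros((n, k))
        assigned = labels >= 0
        onehot[np.flatnonzero(assigned), labels[assigned]] = 1.0
        # neighbor count within +-window, excluding the sample itself
        counts = uniform_filter1d(onehot, size=span, axis=0, mode="constant") * span - onehot
        score = C + weight * counts
        new_labels = score.argmax(axis=1)
        best_score = score[np.arange(n), new_labels]
        new_labels[(~assigned) & (best_score < threshold)] = UNASSIGNED
        new_labels[~eligible] = UNASSIGNED
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return SegmentationResult(
        labels=labels,
        corr=seg.corr,
        sfreq=seg.sfreq,
        params={**seg.params, "smooth_window": window, "smooth_factor": factor},
        seams=seg.seams,
    )


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode: list of (label, start, length)."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _chunks(labels: np.ndarray, seams: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Split a label sequence at epoch-concatenation seams."""
    bounds = [0, *sorted(int(s) for s in seams if 0 < s < labels.size), labels.size]
    return [(bounds[i], labels[bounds[i] : bounds[i + 1]]) for i in range(len(bounds) - 1)]


def enforce_min_duration(
    seg: SegmentationResult,
    rec: EEGRecording | None = None,
    maps: MicrostateMapSet | None = None,
    min_samples: int = 3,
) -> SegmentationResult:
    """Split labeled runs shorter than ``min_samples`` between their neighbors.

    A short run is cut at its midpoint: the left part takes the left
    neighbor's label and the right part the right neighbor's (runs at a
    sequence or seam boundary take their single neighbor's label). Applied
    iteratively until no short labeled run remains. Unassigned stretches are
    not runs and are never relabeled.
    """
    labels = seg.labels.copy()
    if labels.size < min_samples:
        logger.warning("recording shorter than the minimum run duration; left unchanged")
        return seg
    for offset, chunk in _chunks(labels, seg.seams):
        chunk = chunk.copy()
        for _ in range(2 * chunk.size):  # termination: each split removes one run
            runs = _runs(chunk)
            short = next(
                (
                    (i, r)
                    for i, r in enumerate(runs)
                    if r[0] != UNASSIGNED and r[2] < min_samples
                ),
                None,
            )
            if short is None:
                break
            idx, (lab, start, length) = short
            left = runs[idx - 1][0] if idx > 0 else None
            right = runs[idx + 1][0] if idx < len(runs) - 1 else None
            if left is None and right is None:
                break  # whole chunk is one short run; nothing to borrow from
            mid = start + length // 2
            chunk[start:mid] = left if left is not None else right
            chunk[mid : start + length] = right if right is not None else left
        labels[offset : offset + chunk.size] = chunk
    return SegmentationResult(
        labels=labels,
        corr=seg.corr,
        sfreq=seg.sfreq,
        params={**seg.params, "min_duration_samples": min_samples},
        seams=seg.seams,
    )


def compute_measures(
    seg: SegmentationResult, map_labels: list[str] | None = None, n_maps: int | None = None
) -> TemporalMeasures:
    """Occurrence, mean duration, and coverage per map from the final labels.

    Runs touching the recording ends or an epoch seam have censored length
    and are excluded from mean duration, but still count toward occurrence
    and coverage. Coverages plus the unassigned fraction sum to one.
    """
    k = n_maps if n_maps is not None else int(seg.params.get("k", seg.labels.max() + 1))
    map_labels = map_labels or [f"M{i + 1}" for i in range(k)]
    total_samples = seg.labels.size
    total_s = total_samples / seg.sfreq
    n_runs = np.zeros(k)
    interior_lengths: list[list[int]] = [[] for _ in range(k)]
    counts = np.zeros(k)
    for offset, chunk in _chunks(seg.labels, seg.seams):
        for lab, start, length in _runs(chunk):
            if lab == UNASSIGNED:
                continue
            n_runs[lab] += 1
            counts[lab] += length
            if start > 0 and start + length < chunk.size:
                interior_lengths[lab].append(length)
    occurrence = n_runs / total_s
    coverage = counts / total_samples
    mean_dur = np.array(
        [np.mean(ls) if ls else 0.0 for ls in interior_lengths]
    ) / seg.sfreq * 1000.0
    present = n_runs > 0
    unassigned_fraction = float((seg.labels == UNASSIGNED).mean())
    return TemporalMeasures(
        map_labels=list(map_labels),
        occurrence=occurrence,
        mean_duration_ms=mean_dur,
        coverage=coverage,
        present=present,
        unassigned_fraction=unassigned_fraction,
    )


def band_pipeline(
    rec: EEGRecording,
    grand_maps: MicrostateMapSet,
    bands: list[BandSpec] | None = None,
    threshold: float = 0.50,
    window: int = 7,
    factor: float = 10.0,
    min_samples: int = 3,
) -> dict[str, TemporalMeasures]:
    """Filter -> reference -> assign -> smooth -> min-duration -> measures, per band.

    The same (broadband) grand-mean maps are backfitted to every band, so the
    resulting features are directly comparable across bands.
    """
    bands = bands if bands is not None else list(DEFAULT_BANDS.values())
    out: dict[str, TemporalMeasures] = {}
    for band in bands:
        filtered = average_reference(bandpass(rec, band))
        seg = assign_labels(filtered, grand_maps, threshold=threshold)
        seg = smooth_labels(seg, filtered, grand_maps, window=window, factor=factor)
        seg = enforce_min_duration(seg, min_samples=min_samples)
        m = compute_measures(seg, map_labels=grand_maps.labels, n_maps=grand_maps.k)
        if m.unassigned_fraction > 0.5:
            logger.warning(
                "band %s: %.0f%% of samples unassigned (degenerate input?)",
                band.name,
                100 * m.unassigned_fraction,
            )
        out[band.name] = m
    return out
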