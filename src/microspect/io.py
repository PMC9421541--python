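"""Recording and result I/O: CSV matrices, EDF, JSON sidecars, map-set JSON.

CSV recordings are channels x samples with a header row of channel labels.
EDF output uses a minimal single-data-record EDF writer (16-bit samples,
per-channel physical scaling); EDF input goes through mne. Each written
subject gets a JSON sidecar holding the group tag, seed provenance, and a
run-length encoding of the ground-truth label sequence when available.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .backfit import TemporalMeasures
from .clustering import MicrostateMapSet
from .core import EEGRecording

__all__ = [
    "write_csv_recording",
    "read_csv_recording",
    "write_edf",
    "read_edf",
    "write_sidecar",
    "read_sidecar",
    "map_set_to_json",
    "map_set_from_json",
    "measures_to_tidy",
]


def write_csv_recording(rec: EEGRecording, path: str | Path) -> None:
    """Write channels x samples CSV with a channel-label header row."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.6f")


def read_csv_recording(
    path: str | Path, sfreq: float, subject_id: str = "", group: int | None = None
) -> EEGRecording:
    df = pd.read_csv(path)
    return EEGRecording(
        data=df.to_numpy(dtype=float).T,
        sfreq=sfreq,
        channel_labels=list(df.columns),
        subject_id=subject_id or Path(path).stem,
        group=group,
    )


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a minimal EDF file: one data record spanning the whole recording.

    Samples are quantized to 16-bit integers over each channel's physical
    range, the usual EDF precision.
    """
    n_ch, n_samp = rec.n_channels, rec.n_samples
    duration = n_samp / rec.sfreq
    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    span = phys_max - phys_min
    span[span == 0] = 1.0
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _edf_field("0", 8)  # version
    header += _edf_field(rec.subject_id or "X", 80)  # patient id
    header += _edf_field("microspect", 80)  # recording id
    header += _edf_field("01.01.00", 8)  # start date (placeholder)
    header += _edf_field("00.00.00", 8)  # start time
    header += _edf_field(256 + 256 * n_ch, 8)  # header bytes
    header += _edf_field("", 44)  # reserved
    header += _edf_field(1, 8)  # number of data records
    header += _edf_field(f"{duration:.3f}".rstrip("0").rstrip("."), 8)
    header += _edf_field(n_ch, 4)
    for lbl in rec.channel_labels:
        header += _edf_field(f"EEG {lbl}", 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{v:.4f}"[:8], 8) for v in phys_min)
    header += b"".join(_edf_field(f"{v:.4f}"[:8], 8) for v in phys_max)
    header += b"".join(_edf_field(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(_edf_field(n_samp, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))  # reserved

    body = bytearray()
    for ch in range(n_ch):
        scaled = (rec.data[ch] - phys_min[ch]) / span[ch]
        dig = np.round(scaled * (dig_max - dig_min) + dig_min).astype("<i2")
        body += struct.pack(f"<{n_samp}h", *dig)
    Path(path).write_bytes(header + bytes(body))


def read_edf(path: str | Path, subject_id: str = "", group: int | None = None) -> EEGRecording:
    """Read an EDF recording via mne; data returned in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    return EEGRecording(
        data=raw.get_data() * 1e6,
        sfreq=float(raw.info["sfreq"]),
        channel_labels=labels,
        subject_id=subject_id or Path(path).stem,
        group=group,
    )


def _rle(labels: np.ndarray) -> list[list[int]]:
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [[int(labels[s]), int(e - s)] for s, e in zip(starts, ends)]


def rle_decode(runs: list[list[int]]) -> np.ndarray:
    return np.concatenate([np.full(n, lab, dtype=int) for lab, n in runs])


def write_sidecar(
    path: str | Path,
    rec: EEGRecording,
    seed: int | None = None,
    label_sequence: np.ndarray | None = None,
) -> None:
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "sfreq": rec.sfreq,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "seed": seed,
    }
    if label_sequence is not None:
        meta["truth_rle"] = _rle(np.asarray(label_sequence))
    Path(path).write_text(json.dumps(meta, indent=1))


def read_sidecar(path: str | Path) -> dict:
    meta = json.loads(Path(path).read_text())
    if "truth_rle" in meta:
        meta["label_sequence"] = rle_decode(meta["truth_rle"])
    return meta


def map_set_to_json(ms: MicrostateMapSet, path: str | Path | None = None) -> dict:
    d = {
        "labels": list(ms.labels),
        "channel_labels": list(ms.channel_labels),
        "maps": ms.maps.tolist(),
        "k": ms.k,
        "gev": None if np.isnan(ms.gev) else float(ms.gev),
        "level": ms.level,
        "band": ms.band,
    }
    if path is not None:
        Path(path).write_text(json.dumps(d, indent=1))
    return d


def map_set_from_json(source: str | Path | dict) -> MicrostateMapSet:
    d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
    return MicrostateMapSet(
        maps=np.asarray(d["maps"], dtype=float),
        labels=list(d["labels"]),
        channel_labels=list(d["channel_labels"]),
        level=d.get("level", "grand"),
        band=d.get("band", "broadband"),
        gev=float("nan") if d.get("gev") is None else float(d["gev"]),
    )


def measures_to_tidy(
    per_subject: dict[str, tuple[int, dict[str, TemporalMeasures]]]
) -> pd.DataFrame:
    """Flatten {subject_id: (group, {band: TemporalMeasures})} into a tidy table."""
    rows = []
    for subject_id, (group, bands) in per_subject.items():
        for band, tm in bands.items():
            for i, map_label in enumerate(tm.map_labels):
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "band": band,
                        "map": map_label,
                        "occurrence_hz": tm.occurrence[i],
                        "mean_duration_ms": tm.mean_duration_ms[i],
                        "coverage": tm.coverage[i],
                        "unassigned_fraction": tm.unassigned_fraction,
                    }
                )
    return pd.DataFrame(rows)
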