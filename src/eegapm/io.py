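"""Reading and writing recordings and segments.

CSV recordings are plain numeric tables, one row per channel, with the
sampling rate supplied by the caller (it is not stored in the table).  A
JSON sidecar ``<stem>.json`` carries label, subject id, sampling rate and
channel names.  EDF files are read through MNE when the optional ``mne``
dependency is available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CHANNELS_1020, EEGRecord, Segment


def read_csv_record(
    path,
    fs: float,
    channel_names=None,
    subject_id: str = "",
    label: str = "unknown",
) -> EEGRecord:
    """Read a channels-by-samples CSV table (no header) as a recording.

    If a JSON sidecar exists next to the file, its ``fs``, ``label``,
    ``subject_id`` and ``channel_names`` entries override the arguments.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs", fs)
        label = meta.get("label", label)
        subject_id = meta.get("subject_id", subject_id)
        channel_names = meta.get("channel_names", channel_names)
    data = pd.read_csv(
        path, header=None, float_precision="round_trip"
    ).to_numpy(dtype=float)
    if channel_names is None:
        channel_names = list(CHANNELS_1020[: data.shape[0]])
    return EEGRecord(
        data=data, fs=fs, channel_names=list(channel_names),
        subject_id=subject_id, label=label,
    )


def write_csv_record(record: EEGRecord, path) -> None:
    """Write a recording as a headerless CSV plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(record.data).to_csv(
        path, index=False, header=False, float_format="%.17g"
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "fs": record.fs,
        "label": record.label,
        "subject_id": record.subject_id,
        "channel_names": list(record.channel_names),
    }, indent=1))


def read_edf_record(path, label: str = "unknown", subject_id: str = "") -> EEGRecord:
    """Read an EDF file via MNE; channel names and fs come from the header.

    Signal values are converted from volts (MNE convention) to microvolts.
    Channels present in the canonical 10-20 list are reordered to it when
    all 19 are found.
    """
    import mne  # local import: optional dependency, slow to load

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6
    record = EEGRecord(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=subject_id or Path(path).stem,
        label=label,
    )
    if all(name in record.channel_names for name in CHANNELS_1020):
        record = record.reorder_channels()
    return record


def read_record(path, fs: float = None, **kwargs) -> EEGRecord:
    """Dispatch on extension: ``.edf`` via MNE, otherwise CSV (needs fs
    unless a sidecar provides it)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf_record(path, **kwargs)
    if fs is None and not path.with_suffix(".json").exists():
        raise ValueError("CSV input requires a sampling rate or JSON sidecar")
    return read_csv_record(path, fs=fs if fs is not None else 0.0, **kwargs)


def write_segments(segments, out_dir) -> list:
    """Write each segment as CSV + JSON sidecar; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for seg in segments:
        stem = f"{seg.subject_id or 'rec'}_seg{seg.segment_index:03d}"
        path = out_dir / f"{stem}.csv"
        pd.DataFrame(seg.data).to_csv(
            path, index=False, header=False, float_format="%.17g"
        )
        path.with_suffix(".json").write_text(json.dumps({
            "fs": seg.fs,
            "label": seg.label,
            "subject_id": seg.subject_id,
            "segment_index": seg.segment_index,
        }, indent=1))
        paths.append(path)
    return paths


def read_segments(in_dir) -> list:
    """Load every ``*_seg*.csv`` (with sidecar) from a directory."""
    in_dir = Path(in_dir)
    segments = []
    for path in sorted(in_dir.glob("*_seg*.csv")):
        meta = json.loads(path.with_suffix(".json").read_text())
        segments.append(Segment(
            data=pd.read_csv(
                path, header=None, float_precision="round_trip"
            ).to_numpy(dtype=float),
            fs=meta["fs"],
            label=meta.get("label", "unknown"),
            subject_id=meta.get("subject_id", ""),
            segment_index=meta.get("segment_index", 0),
        ))
    return segments
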