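"""Channel fusion: concatenate per-channel BPFSL vectors into one row per
segment, and the labeled feature-matrix container used downstream."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bpfsl import N_BINS, channel_features
from .preprocess import CHANNELS_1020


def feature_names(channel_names=CHANNELS_1020, n_bins: int = N_BINS) -> list:
    """Column names ``ch<electrode>_bin<code>`` in fused order."""
    return [
        f"ch{ch}_bin{b:02d}" for ch in channel_names for b in range(n_bins)
    ]


def fuse_channels(per_channel) -> np.ndarray:
    """Concatenate per-channel vectors; feature j of channel i lands at
    index ``i * 32 + j``."""
    arrays = [np.asarray(v, dtype=float) for v in per_channel]
    if not arrays:
        raise ValueError("need at least one channel vector")
    lengths = {a.shape for a in arrays}
    if lengths != {(N_BINS,)}:
        raise ValueError(f"every channel vector must have length {N_BINS}")
    return np.concatenate(arrays)


def split_channels(fused) -> list:
    """Inverse of :func:`fuse_channels`: recover the per-channel 32-vectors."""
    fused = np.asarray(fused, dtype=float)
    if fused.ndim != 1 or fused.size % N_BINS:
        raise ValueError(f"fused length must be a multiple of {N_BINS}")
    return [fused[i:i + N_BINS] for i in range(0, fused.size, N_BINS)]


@dataclass
class FeatureMatrix:
    """Fused features for a set of segments, with labels and provenance."""

    values: np.ndarray
    feature_names: list
    labels: np.ndarray
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (segments x features)")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("one name per feature column required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("one label per row required")
        if self.subject_ids is None:
            self.subject_ids = np.array([""] * self.values.shape[0])
        self.subject_ids = np.asarray(self.subject_ids)

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df["subject_id"] = self.subject_ids
        return df

    def to_csv(self, path) -> None:
        # 17 significant digits round-trips IEEE doubles exactly.
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        names = [c for c in df.columns if c not in ("label", "subject_id")]
        return cls(
            values=df[names].to_numpy(dtype=float),
            feature_names=names,
            labels=df["label"].to_numpy(),
            subject_ids=df["subject_id"].astype(str).to_numpy()
            if "subject_id" in df else None,
        )


def segments_to_features(
    segments,
    channel_names=CHANNELS_1020,
    gamma_divisor: float = 16.0,
    prescale: float = 1.0,
    normalize: bool = False,
) -> FeatureMatrix:
    """Extract and fuse BPFSL features for a list of segments (one row each)."""
    if not segments:
        raise ValueError("need at least one segment")
    rows, labels, subjects = [], [], []
    for seg in segments:
        per_channel = [
            channel_features(
                seg.data[c],
                gamma_divisor=gamma_divisor,
                prescale=prescale,
                normalize=normalize,
            )
            for c in range(seg.n_channels)
        ]
        rows.append(fuse_channels(per_channel))
        labels.append(seg.label)
        subjects.append(seg.subject_id)
    names = feature_names(channel_names[: segments[0].n_channels])
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        labels=np.array(labels),
        subject_ids=np.array(subjects),
    )
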