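"""EEG input containers, band-pass / notch filtering and fixed-length segmentation.

A recording is held as a channels-by-samples matrix in microvolts together
with its sampling rate and the ordered 10-20 electrode labels.  Filtering is
zero-phase FIR (forward-backward application) so that segment-local features
downstream are not time-shifted.  Recordings are cut into non-overlapping
fixed-duration windows; a trailing partial window is dropped so every segment
yields the same number of features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: Canonical 19-electrode 10-20 montage order used throughout the package.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

VALID_LABELS = ("R", "NR", "unknown")


@dataclass
class EEGRecord:
    """A labeled multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts, one row per channel.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Electrode labels, one per row of ``data``.
    subject_id : str
        Opaque subject identifier.
    label : {"R", "NR", "unknown"}
        Responder / non-responder class, if known.
    """

    data: np.ndarray
    fs: float
    channel_names: list = field(default_factory=lambda: list(CHANNELS_1020))
    subject_id: str = ""
    label: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one channel")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def reorder_channels(self, order=CHANNELS_1020) -> "EEGRecord":
        """Return a copy with rows rearranged into the canonical montage order."""
        name_to_row = {name: i for i, name in enumerate(self.channel_names)}
        missing = [name for name in order if name not in name_to_row]
        if missing:
            raise ValueError(f"channels missing from record: {missing}")
        rows = [name_to_row[name] for name in order]
        return replace(self, data=self.data[rows], channel_names=list(order))


@dataclass
class Segment:
    """One fixed-duration window cut from an :class:`EEGRecord`."""

    data: np.ndarray
    fs: float
    label: str = "unknown"
    subject_id: str = ""
    segment_index: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("segment data must be 2-D")
        if self.segment_index < 0:
            raise ValueError("segment_index must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _fir_numtaps(fs: float, low_hz: float, cap: int = 1023) -> int:
    """FIR length heuristic: ~3 periods of the low cutoff, capped, forced odd."""
    n = int(round(3.0 * fs / low_hz))
    n = min(n, cap)
    if n % 2 == 0:
        n += 1
    return max(n, 11)


def _apply_filtfilt(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    padlen = min(3 * len(taps), data.shape[1] - 1)
    return signal.filtfilt(taps, [1.0], data, axis=1, padlen=padlen)


def bandpass_filter(
    record: EEGRecord, low_hz: float = 0.5, high_hz: float = 45.0
) -> EEGRecord:
    """Zero-phase FIR band-pass.

    Channel means are removed before filtering so DC is rejected exactly even
    when the FIR transition band is wide relative to the low cutoff.
    """
    if not (0.0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= record.fs / 2:
        raise ValueError(
            f"high cutoff {high_hz} Hz is at or above Nyquist ({record.fs / 2} Hz)"
        )
    numtaps = _fir_numtaps(record.fs, low_hz)
    taps = signal.firwin(
        numtaps, [low_hz, high_hz], pass_zero=False, fs=record.fs
    )
    centered = record.data - record.data.mean(axis=1, keepdims=True)
    filtered = _apply_filtfilt(centered, taps)
    return replace(record, data=filtered)


def notch_filter(
    record: EEGRecord, stop_low_hz: float = 47.0, stop_high_hz: float = 53.0
) -> EEGRecord:
    """Zero-phase FIR band-stop, default 47-53 Hz for 50 Hz mains rejection."""
    if not (0.0 < stop_low_hz < stop_high_hz):
        raise ValueError("need 0 < stop_low_hz < stop_high_hz")
    if stop_high_hz >= record.fs / 2:
        raise ValueError(
            f"stop band edge {stop_high_hz} Hz is at or above Nyquist "
            f"({record.fs / 2} Hz)"
        )
    # Length tied to the stop-band width so the notch is deep at band center.
    width = stop_high_hz - stop_low_hz
    numtaps = _fir_numtaps(record.fs, width / 2.0)
    taps = signal.firwin(
        numtaps, [stop_low_hz, stop_high_hz], pass_zero=True, fs=record.fs
    )
    filtered = _apply_filtfilt(record.data, taps)
    return replace(record, data=filtered)


def segment(record: EEGRecord, seconds: float = 15.0) -> list:
    """Cut a record into consecutive non-overlapping windows.

    Returns ``floor(duration / seconds)`` segments; a trailing partial window
    is discarded.  Each segment inherits the record's label and subject id.
    """
    if seconds <= 0:
        raise ValueError("segment duration must be positive")
    win = int(round(record.fs * seconds))
    n_seg = record.n_samples // win
    if n_seg == 0:
        logger.warning(
            "record %s shorter than one %.3g-s window; returning no segments",
            record.subject_id, seconds,
        )
        return []
    return [
        Segment(
            data=record.data[:, i * win:(i + 1) * win].copy(),
            fs=record.fs,
            label=record.label,
            subject_id=record.subject_id,
            segment_index=i,
        )
        for i in range(n_seg)
    ]
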