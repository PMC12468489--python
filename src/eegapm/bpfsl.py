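"""Binary pattern of five successive lines (BPFSL) histogram features.

Six consecutive trajectory points define five line segments.  The five
segment lengths in each sliding window are compared against a window-local
threshold gamma = population-std / divisor (default divisor 2**4 = 16);
each comparison yields one bit (ties count as 1) and the five bits pack
into a code in 0..31.  The per-channel feature vector is the 32-bin
histogram of these codes, so a channel of N samples contributes exactly
N - 6 codes: N-1 trajectory points, N-2 distances, (N-2) - 4 windows.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .mapping import APMTrajectory, apm_map

#: Number of histogram bins == number of distinct 5-bit codes.
N_BINS = 32

WINDOW = 5

_BIT_WEIGHTS = 2 ** np.arange(WINDOW)


def point_distances(traj: APMTrajectory) -> np.ndarray:
    """Euclidean distances between consecutive trajectory points."""
    if traj.n_points < 2:
        raise ValueError("need at least 2 trajectory points")
    return np.hypot(np.diff(traj.x), np.diff(traj.y))


def code_from_bits(bits) -> int:
    """Pack five threshold bits (index i weighted by 2**i) into a code."""
    bits = np.asarray(bits, dtype=int)
    if bits.shape != (WINDOW,):
        raise ValueError(f"expected {WINDOW} bits")
    return int(bits @ _BIT_WEIGHTS)


def bpfsl_codes(A, gamma_divisor: float = 16.0) -> np.ndarray:
    """Five-bit codes for every window of 5 consecutive distances.

    bit i = 1  iff  A[n+i] >= gamma(n),  gamma(n) = pop-std(window) / divisor.

    A window of equal distances has zero spread, gamma = 0, and all five
    comparisons tie to 1, giving code 31.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 1 or A.size < WINDOW:
        raise ValueError(f"need at least {WINDOW} distances")
    if gamma_divisor <= 0:
        raise ValueError("gamma_divisor must be positive")
    windows = sliding_window_view(A, WINDOW)
    gamma = windows.std(axis=1) / gamma_divisor  # population std (ddof=0)
    bits = windows >= gamma[:, None]
    return bits @ _BIT_WEIGHTS


def bpfsl_histogram(codes) -> np.ndarray:
    """32-bin histogram of code multiplicities (zero bins included)."""
    codes = np.asarray(codes, dtype=int)
    if codes.size < 1:
        raise ValueError("need at least one code")
    if codes.min() < 0 or codes.max() >= N_BINS:
        raise ValueError("codes out of range 0..31")
    return np.bincount(codes, minlength=N_BINS)


def channel_features(
    a,
    gamma_divisor: float = 16.0,
    prescale: float = 1.0,
    normalize: bool = False,
) -> np.ndarray:
    """32-element BPFSL feature vector for one channel.

    Composition: APM trajectory -> inter-point distances -> 5-bit codes ->
    32-bin histogram.  In counts mode (default) the vector sums to N - 6
    for an N-sample channel; with ``normalize`` the counts are divided by
    their total so segment length drops out.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size < 8:
        raise ValueError("need a 1-D channel of at least 8 samples")
    traj = apm_map(a, prescale=prescale)
    A = point_distances(traj)
    codes = bpfsl_codes(A, gamma_divisor=gamma_divisor)
    hist = bpfsl_histogram(codes)
    if normalize:
        return hist / hist.sum()
    return hist
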