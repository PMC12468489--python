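"""2-D trajectory mappings of a single EEG channel.

The amplitude-polar map (APM) takes the first difference ``a'`` of the
signal and plots ``a' * sin(a')`` against ``a' * cos(a')``: amplitude
increments act both as the radius and as the (radian) angle of each point,
so slow variations collapse near the origin while fast fluctuations sweep
wide arcs.  Second-order difference plots (SODP) and delay embeddings (phase
space reconstruction, PSR) are provided as classical baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class APMTrajectory:
    """A planar point sequence; ``x[k]**2 + y[k]**2`` equals the squared
    amplitude increment that generated point ``k`` (APM case)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    @property
    def n_points(self) -> int:
        return self.x.size


def differential(a) -> np.ndarray:
    """First-order difference ``a[k+1] - a[k]``; length ``N - 1``."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need a 1-D signal of at least 2 samples")
    return np.diff(a)


def apm_map(a, prescale: float = 1.0) -> APMTrajectory:
    """Amplitude-polar map of a channel.

    The increments are used as radian angles directly (microvolts read as
    radians, no unit rescaling); ``prescale`` multiplies the increments
    first and defaults to 1 so the map is applied to raw amplitudes.
    """
    d = differential(a) * prescale
    return APMTrajectory(x=d * np.sin(d), y=d * np.cos(d))


def sodp_map(a) -> APMTrajectory:
    """Second-order difference plot: successive increments against each
    other; length ``N - 2``."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size < 3:
        raise ValueError("need a 1-D signal of at least 3 samples")
    d = np.diff(a)
    return APMTrajectory(x=d[:-1], y=d[1:])


def psr_embed(a, dim: int = 2, delay: int = 1) -> np.ndarray:
    """Delay embedding: rows ``[a[n], a[n+tau], ..., a[n+(m-1)tau]]``.

    Returns an ``(N - (m-1)*tau, m)`` matrix.
    """
    a = np.asarray(a, dtype=float)
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    if delay < 1:
        raise ValueError("delay must be >= 1")
    n_rows = a.size - (dim - 1) * delay
    if a.ndim != 1 or n_rows < 1:
        raise ValueError(
            f"signal of {a.size} samples too short for dim={dim}, delay={delay}"
        )
    idx = np.arange(n_rows)[:, None] + delay * np.arange(dim)[None, :]
    return a[idx]
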