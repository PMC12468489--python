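"""Multiscale PCA denoising of multichannel EEG segments.

Each channel is decomposed with a discrete wavelet transform to depth ``J``.
At every coefficient level the channels-by-coefficients matrix is truncated
by PCA, keeping the principal components whose eigenvalues exceed the mean
eigenvalue (Kaiser rule).  Detail levels where no component survives are
zeroed outright.  The channels are then rebuilt by the inverse transform and
a final Kaiser-rule PCA pass is applied to the reconstructed matrix.

The procedure assumes the clean multichannel signal is low-rank across
channels (shared cortical sources scaled per electrode) while noise is
spatially incoherent, so discarding sub-average eigendirections removes
mostly noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt

from .preprocess import Segment


@dataclass
class MSPCAConfig:
    """Settings for :func:`mspca_denoise`.

    Parameters
    ----------
    wavelet_name : str
        Any discrete wavelet known to PyWavelets; ``sym4`` is a common
        choice for EEG.
    level_J : int
        Decomposition depth; the segment must hold at least ``2**level_J``
        samples.
    final_pca : bool
        Apply the closing Kaiser-rule PCA to the reconstructed matrix.
    mode : str
        Wavelet boundary extension mode.
    """

    wavelet_name: str = "sym4"
    level_J: int = 5
    final_pca: bool = True
    mode: str = "symmetric"

    def __post_init__(self):
        if self.level_J < 1:
            raise ValueError("level_J must be >= 1")


def kaiser_retain(cov_eigenvalues) -> np.ndarray:
    """Indices of eigenvalues strictly greater than their arithmetic mean.

    May be empty (e.g. when all eigenvalues are equal, since the comparison
    is strict).
    """
    eig = np.asarray(cov_eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("need at least one eigenvalue")
    return np.flatnonzero(eig > eig.mean())


def _pca_truncate(coeffs: np.ndarray) -> tuple[np.ndarray, int]:
    """Kaiser-rule PCA truncation of a channels x n coefficient matrix.

    Observations are the ``n`` coefficient vectors across channels; each
    channel is mean-centered first.  Returns the truncated matrix and the
    number of retained components (0 means the level carried no
    above-average eigendirection and the output is the per-channel mean
    only).
    """
    mean = coeffs.mean(axis=1, keepdims=True)
    centered = coeffs - mean
    cov = centered @ centered.T / max(coeffs.shape[1] - 1, 1)
    eigval, eigvec = np.linalg.eigh(cov)
    # eigh returns ascending order; orient to descending for readability
    eigval = eigval[::-1]
    eigvec = eigvec[:, ::-1]
    keep = kaiser_retain(np.clip(eigval, 0.0, None))
    if keep.size == 0:
        return np.broadcast_to(mean, coeffs.shape).copy(), 0
    V = eigvec[:, keep]
    # Fix eigenvector sign: largest-magnitude loading positive.
    for j in range(V.shape[1]):
        pivot = np.argmax(np.abs(V[:, j]))
        if V[pivot, j] < 0:
            V[:, j] = -V[:, j]
    return V @ (V.T @ centered) + mean, keep.size


def mspca_denoise(seg: Segment, config: MSPCAConfig | None = None) -> Segment:
    """Denoise one segment by multiscale PCA.

    Detail levels whose Kaiser set is empty are zeroed; the approximation
    level keeps its retained components.  Output has the same shape as the
    input and the pipeline is deterministic.
    """
    if config is None:
        config = MSPCAConfig()
    data = seg.data
    if data.shape[1] < 2 ** config.level_J:
        raise ValueError(
            f"segment of {data.shape[1]} samples too short for level "
            f"{config.level_J} decomposition"
        )
    coeffs = pywt.wavedec(
        data, config.wavelet_name, level=config.level_J, mode=config.mode, axis=1
    )
    # coeffs[0] is the approximation at depth J, the rest are details.
    approx, _ = _pca_truncate(coeffs[0])
    new_coeffs = [approx]
    for det in coeffs[1:]:
        truncated, n_kept = _pca_truncate(det)
        new_coeffs.append(truncated if n_kept > 0 else np.zeros_like(det))
    recon = pywt.waverec(new_coeffs, config.wavelet_name, mode=config.mode, axis=1)
    recon = recon[:, : data.shape[1]]
    if config.final_pca:
        recon, _ = _pca_truncate(recon)
    return replace(seg, data=recon)
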