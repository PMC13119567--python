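"""Sliding-window channel embedding and ZCA whitening of a complex echo.

A 1xN slow-time sequence is embedded into an M-channel matrix whose rows are
successively delayed copies of the signal (a Hankel-style embedding).  ZCA
("zero-phase") whitening then decorrelates the channels to unit variance while
rotating back into the original channel frame, W = U (L)^(-1/2) U^H, so each
row of Z = W X_bar is a zero-phase component of the echo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChannelMatrix", "WhitenedSet", "embed", "zca_whiten"]


@dataclass
class ChannelMatrix:
    """M x K delayed-channel embedding of a length-N sequence (K = N - M + 1)."""

    data: np.ndarray
    means: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def centered(self) -> np.ndarray:
        return self.data - self.means[:, None]


@dataclass
class WhitenedSet:
    """Whitened components Z (M x K) with the transform that produced them.

    ``whitening_matrix`` is W, ``unmixing_inverse`` is W^-1 (maps components
    back to physical channel units), ``eigenvalues``/``eigenvectors`` are the
    spectral factors of the channel covariance.
    """

    components: np.ndarray
    whitening_matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    unmixing_inverse: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def component_amplitudes(self) -> np.ndarray:
        """Physical amplitude of each component: the time-mean magnitude of
        its back-projected contribution to the embedding channels,
        rms_channels(W^-1[:, j]) * mean_t |z_j(t)|.

        Whitened rows all have unit variance by construction, so their raw
        magnitudes carry no scale information; back-projection restores the
        echo's physical units and makes the amplitudes comparable with the
        per-segment RCS weights.
        """
        w = np.linalg.norm(self.unmixing_inverse, axis=0) / np.sqrt(
            self.unmixing_inverse.shape[0]
        )
        return w * np.mean(np.abs(self.components), axis=1)


def embed(echo: np.ndarray, channels: int) -> ChannelMatrix:
    """Embed a length-N complex sequence into ``channels`` delayed rows.

    Row i (0-based) is echo[i : i + K] with K = N - channels + 1; the
    embedding is lossless (first row + last column reproduce the input).
    """
    x = np.asarray(echo)
    if x.ndim != 1:
        raise ValueError("echo must be one-dimensional")
    n = x.size
    m = int(channels)
    if m < 2:
        raise ValueError("need at least 2 channels")
    if m >= n:
        raise ValueError("number of channels must be smaller than the echo length")
    k = n - m + 1
    data = np.lib.stride_tricks.sliding_window_view(x, k)[:m].copy()
    return ChannelMatrix(data=data, means=data.mean(axis=1))


def zca_whiten(
    cm: ChannelMatrix,
    eig_floor: float = 1e-10,
    whitening: str = "pca",
) -> WhitenedSet:
    """Whiten the centered channel matrix to identity channel covariance.

    The M x M channel covariance Sigma = X_bar X_bar^H / (K - 1) is
    eigendecomposed.  The default ``'pca'`` transform
    W = (L + floor)^(-1/2) U^H projects into the eigenbasis, ordered by
    descending eigenvalue, so each unit-variance component is an eigen-
    filtered (frequency-band-like) view of the echo — this is the form that
    actually separates torso and feet returns, and the component indices it
    produces are eigenvalue ranks.  ``whitening='zca'`` uses the Hermitian
    zero-phase form W = U (L + floor)^(-1/2) U^H, which rotates back to the
    channel frame; its components remain near-copies of the delayed channels
    and are kept for completeness.  ``eig_floor`` is relative to the largest
    eigenvalue and regularizes rank-deficient covariances.
    """
    if whitening not in ("zca", "pca"):
        raise ValueError("whitening must be 'zca' or 'pca'")
    xb = cm.centered
    if not np.any(xb):
        raise ValueError("all-zero input cannot be whitened")
    k = xb.shape[1]
    sigma = xb @ xb.conj().T / (k - 1)
    evals, evecs = np.linalg.eigh(sigma)
    evals = np.maximum(evals.real, 0.0)
    order = np.argsort(evals)[::-1]  # strongest component first
    evals, evecs = evals[order], evecs[:, order]
    floor = eig_floor * float(evals.max())
    inv_sqrt = 1.0 / np.sqrt(evals + floor)
    if whitening == "zca":
        w = (evecs * inv_sqrt) @ evecs.conj().T
        w_inv = (evecs * np.sqrt(evals + floor)) @ evecs.conj().T
    else:
        w = inv_sqrt[:, None] * evecs.conj().T
        w_inv = evecs * np.sqrt(evals + floor)
    z = w @ xb
    return WhitenedSet(
        components=z,
        whitening_matrix=w,
        eigenvalues=evals,
        eigenvectors=evecs,
        unmixing_inverse=w_inv,
    )
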