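"""Sliding-window state-space (Hankel/SVD) instantaneous-frequency tracking.

Within each length-n window the signal is arranged into a Hankel matrix
H[r, c] = x[r + c] whose rank equals the number of exponential modes.  The
dominant-subspace factor Omega = U_sn Sigma_sn^(1/2) is shift-invariant, so
the state-transition matrix A solves Omega[:-1] A = Omega[1:] in the least-
squares sense and its eigenvalues are the signal poles.  Sliding the window
one sample at a time yields a pole sequence of length N - n + 1, converted to
decay rates alpha = -ln|lambda| / dt and instantaneous frequencies / radial
velocities.

Sign convention: frequencies are +arg(lambda) / (2 pi dt), chosen so that a
scatterer approaching the radar (decreasing range under the echo phase
-4 pi f r / c) maps to a positive Doppler frequency and positive velocity.

The order-1 tracker (the preprocessing pipeline's work-horse) has a batched
power-iteration fast path; the traditional order-k method with knee-point
order selection is provided as a baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.constants import c as C_LIGHT

__all__ = [
    "SSMConfig",
    "VelocityTrack",
    "build_hankel",
    "estimate_transition",
    "transition_poles",
    "track",
    "knee_point_order",
    "baseline_traditional_ssm",
    "rank_tracks_by_reference",
]


@dataclass
class SSMConfig:
    """Tracker configuration.

    window_len: sliding-window length n [samples].
    hankel_cols: l = floor(n/2) by default.
    order: model order sn (1 for the whitened-component pipeline).
    sample_interval, carrier_freq: map pole phases to Hz and m/s.
    """

    window_len: int = 200
    sample_interval: float = 1.0 / 2000.0
    carrier_freq: float = 15e9
    order: int = 1
    hankel_cols: int | None = None
    step: int = 1  # fixed at 1; the track length contract is N - n + 1

    def __post_init__(self) -> None:
        if self.hankel_cols is None:
            self.hankel_cols = self.window_len // 2
        n, l = self.window_len, self.hankel_cols
        if not 1 <= l <= n - 1:
            raise ValueError("hankel_cols must lie in [1, window_len - 1]")
        if not 1 <= self.order <= min(l, n - l + 1) - 1:
            raise ValueError("order incompatible with the Hankel shape")
        if self.step != 1:
            raise ValueError("step is fixed at 1 sample")


@dataclass
class VelocityTrack:
    """Time-stamped pole trajectory of one echo component.

    For order 1 the arrays are 1-D of length N - n + 1; timestamps are window
    centers.  ``velocities`` are radial, approach-positive [m/s].
    """

    times: np.ndarray
    eigenvalues: np.ndarray
    frequencies: np.ndarray
    velocities: np.ndarray
    decays: np.ndarray

    def __len__(self) -> int:
        return self.times.size

    @property
    def speeds(self) -> np.ndarray:
        return np.abs(self.velocities)


def build_hankel(segment: np.ndarray, l: int) -> np.ndarray:
    """Hankel matrix of a window: (n - l + 1) x l with H[r, c] = x[r + c]."""
    x = np.asarray(segment)
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    if not 1 <= l <= n - 1:
        raise ValueError("l must lie in [1, n - 1]")
    return np.lib.stride_tricks.sliding_window_view(x, l)[: n - l + 1].copy()


def estimate_transition(h: np.ndarray, sn: int = 1, split: str = "balanced") -> np.ndarray:
    """State-transition matrix A (sn x sn) from a Hankel matrix.

    Truncated SVD H ~ U_sn S_sn V_sn^H; the observability factor is
    Omega = U_sn S_sn^(1/2) (balanced square-root split; the pole estimates
    are invariant to the split, ``split='left'`` uses Omega = U_sn).  A is the
    least-squares solution of Omega[:-1] A = Omega[1:].
    """
    h = np.asarray(h)
    if h.shape[0] < 2:
        raise ValueError("Hankel matrix needs at least two rows")
    if not np.any(h):
        raise ValueError("all-zero window")
    u, s, _ = np.linalg.svd(h, full_matrices=False)
    u = u[:, :sn]
    if split == "balanced":
        omega = u * np.sqrt(s[:sn])
    elif split == "left":
        omega = u
    else:
        raise ValueError("split must be 'balanced' or 'left'")
    a, *_ = np.linalg.lstsq(omega[:-1], omega[1:], rcond=None)
    return a


def transition_poles(h: np.ndarray, sn: int = 1) -> np.ndarray:
    """Signal poles: eigenvalues of the estimated transition matrix."""
    return np.linalg.eigvals(estimate_transition(h, sn))


def _pole_outputs(lam: np.ndarray, dt: float, fc: float):
    freqs = np.angle(lam) / (2 * np.pi * dt)
    vels = freqs * C_LIGHT / (2 * fc)
    decays = -np.log(np.maximum(np.abs(lam), 1e-300)) / dt
    return freqs, vels, decays


def _rank1_poles_batched(
    x: np.ndarray,
    n: int,
    l: int,
    n_iter: int = 3,
    block: int = 2,
    chunk: int = 1024,
) -> np.ndarray:
    """Dominant pole of every length-n window via batched subspace iteration.

    Each window's Hankel matrix is a slice of the global one, so all windows
    are processed as one strided 3-D batch.  A ``block``-dimensional subspace
    iteration (matched-filter start plus a fixed pseudo-random companion
    direction) followed by an exact SVD of the projected ``block`` x ``l``
    matrix yields the leading left singular vector, whose shift invariance
    gives the rank-1 pole.  Single precision is ample for pole phases.
    """
    rows = n - l + 1
    g = np.lib.stride_tricks.sliding_window_view(x, l)  # (N - l + 1, l)
    n_win = x.size - n + 1
    rng = np.random.default_rng(0)  # fixed: deterministic tie-breaking only
    extra = rng.standard_normal((l, block - 1)) + 1j * rng.standard_normal(
        (l, block - 1)
    )
    out = np.empty(n_win, dtype=np.complex128)
    for start in range(0, n_win, chunk):
        stop = min(start + chunk, n_win)
        idx = np.arange(start, stop)
        hb = np.lib.stride_tricks.sliding_window_view(g[: x.size - l + 1], (rows, l))[
            idx, 0
        ]
        hb = np.ascontiguousarray(hb).astype(np.complex64)
        nb = stop - start
        v = np.empty((nb, l, block), dtype=np.complex64)
        v[:, :, 0] = np.conj(hb[:, 0, :])
        v[:, :, 1:] = extra.astype(np.complex64)[None]
        for _ in range(n_iter):
            u = hb @ v
            u, _ = np.linalg.qr(u)
            v = np.conj(np.transpose(hb, (0, 2, 1))) @ u
            v, _ = np.linalg.qr(v)
        u = hb @ v
        u, _ = np.linalg.qr(u)
        t = np.conj(np.transpose(u, (0, 2, 1))) @ hb  # (nb, block, l)
        tt = t @ np.conj(np.transpose(t, (0, 2, 1)))  # (nb, block, block)
        evals, evecs = np.linalg.eigh(tt)
        w = evecs[:, :, -1]  # top left vector in the projected basis
        u_top = (u @ w[..., None])[..., 0].astype(np.complex128)
        num = (u_top[:, :-1].conj() * u_top[:, 1:]).sum(axis=1)
        den = (u_top[:, :-1].conj() * u_top[:, :-1]).sum(axis=1)
        out[start:stop] = num / (den + 1e-300)
    return out


def track(echo: np.ndarray, cfg: SSMConfig, method: str = "auto") -> VelocityTrack:
    """Slide the state-space estimator over the echo (step 1 sample).

    Returns one pole per window for order 1 (shape N - n + 1) or all ``order``
    poles per window (shape (N - n + 1, order)).  Window timestamps are
    centered: t_w = (w + n/2) * dt.  ``method='svd'`` forces the exact
    per-window SVD; ``'power'`` the batched rank-1 fast path (order 1 only);
    ``'auto'`` picks power iteration for order 1.
    """
    x = np.asarray(echo)
    n, l, sn = cfg.window_len, cfg.hankel_cols, cfg.order
    if n > x.size:
        raise ValueError("window longer than the echo")
    n_win = x.size - n + 1
    if method == "auto":
        method = "power" if sn == 1 else "svd"
    if method == "power":
        if sn != 1:
            raise ValueError("power iteration path supports order 1 only")
        lam = _rank1_poles_batched(x, n, l)
    elif method == "svd":
        lam = np.empty((n_win, sn), dtype=np.complex128)
        for w in range(n_win):
            lam[w] = transition_poles(build_hankel(x[w : w + n], l), sn)
        if sn == 1:
            lam = lam[:, 0]
    else:
        raise ValueError("method must be 'auto', 'power' or 'svd'")
    times = (np.arange(n_win) + n / 2) * cfg.sample_interval
    freqs, vels, decays = _pole_outputs(lam, cfg.sample_interval, cfg.carrier_freq)
    return VelocityTrack(times, lam, freqs, vels, decays)


def knee_point_order(singular_values: np.ndarray) -> int:
    """Model order at the knee of a descending singular-value spectrum.

    The knee is the point of maximum perpendicular distance between the
    (normalized) singular-value curve and the chord joining its first and
    last points; whether that point is the last signal value or the first
    noise value is resolved by comparing the spectral gaps on either side.
    A flat spectrum has no knee and returns 1 with a warning.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size < 3:
        raise ValueError("need at least three singular values")
    y = s / max(s[0], 1e-300)
    x = np.arange(s.size, dtype=float)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    denom = np.hypot(x1 - x0, y1 - y0)
    d = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / denom
    if np.max(d) < 1e-12:
        warnings.warn("flat singular-value spectrum; returning order 1", stacklevel=2)
        return 1
    k = int(np.argmax(d))
    eps = 1e-300
    gap_right = (s[k] + eps) / (s[k + 1] + eps) if k + 1 < s.size else 1.0
    gap_left = (s[k - 1] + eps) / (s[k] + eps) if k > 0 else np.inf
    return k + 1 if gap_right >= gap_left else max(k, 1)


def _greedy_match(prev_freqs: np.ndarray, new_freqs: np.ndarray) -> np.ndarray:
    """Greedy nearest-frequency association; ties go to the lowest index.

    Returns perm such that new_freqs[perm[j]] continues track j.
    """
    sn = prev_freqs.size
    cost = np.abs(prev_freqs[:, None] - new_freqs[None, :])
    perm = np.full(sn, -1, dtype=int)
    used_r = np.zeros(sn, dtype=bool)
    used_c = np.zeros(sn, dtype=bool)
    for _ in range(sn):
        masked = np.where(used_r[:, None] | used_c[None, :], np.inf, cost)
        r, c = np.unravel_index(np.argmin(masked), masked.shape)
        perm[r] = c
        used_r[r] = True
        used_c[c] = True
    return perm


def baseline_traditional_ssm(
    echo: np.ndarray, cfg: SSMConfig, order: int | None = None
) -> list[VelocityTrack]:
    """Traditional order-k state-space tracking of the raw echo.

    The order defaults to the knee point of the first window's Hankel
    singular values.  Each window contributes ``order`` poles, associated
    into continuous tracks by greedy nearest-frequency matching between
    consecutive windows; returns one VelocityTrack per model order.
    """
    x = np.asarray(echo)
    n, l = cfg.window_len, cfg.hankel_cols
    if order is None:
        sv = np.linalg.svd(build_hankel(x[:n], l), compute_uv=False)
        order = knee_point_order(sv)
    cfg_k = replace(cfg, order=order)
    raw = track(x, cfg_k, method="svd")
    lam = np.atleast_2d(raw.eigenvalues)
    if order == 1:
        lam = lam.reshape(-1, 1)
    n_win = lam.shape[0]
    dt, fc = cfg.sample_interval, cfg.carrier_freq
    assoc = np.empty_like(lam)
    assoc[0] = lam[0][np.argsort(np.angle(lam[0]))]
    for w in range(1, n_win):
        prev_f = np.angle(assoc[w - 1])
        perm = _greedy_match(prev_f, np.angle(lam[w]))
        assoc[w] = lam[w][perm]
    times = raw.times
    tracks = []
    for j in range(order):
        freqs, vels, decays = _pole_outputs(assoc[:, j], dt, fc)
        tracks.append(VelocityTrack(times, assoc[:, j], freqs, vels, decays))
    return tracks


def rank_tracks_by_reference(
    tracks: list[VelocityTrack],
    ref_times: np.ndarray,
    ref_velocities: np.ndarray,
) -> list[int]:
    """Order track indices by closeness to a reference velocity curve.

    The stand-in for the manual curve selection of the traditional method:
    tracks are ranked by the mean absolute velocity difference against the
    reference interpolated onto the track timestamps.
    """
    scores = []
    for j, tr in enumerate(tracks):
        ref = np.interp(tr.times, ref_times, ref_velocities)
        scores.append((float(np.mean(np.abs(tr.velocities - ref))), j))
    scores.sort()
    return [j for _, j in scores]
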