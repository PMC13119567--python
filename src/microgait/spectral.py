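"""Spectrograms, frequency probability densities and the 3-center search.

Each zero-phase component is summarized by a frequency probability density:
its spectrogram magnitude normalized per frame and averaged over time.  An
exhaustive search over all C(M,3) center triples then picks the three
components that minimize the total nearest-center Euclidean distance of the
remaining M-3 densities; the centers are labelled torso / other / feet by
descending physical amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal.windows import hamming

__all__ = [
    "Spectrogram",
    "FreqDensity",
    "SearchResult",
    "stft",
    "freq_density",
    "search_centers",
]

#: Guard for the exhaustive search: C(M,3) enumeration only (no k-medoids
#: shortcut), so component counts are capped.
MAX_SEARCH_COMPONENTS = 32


@dataclass
class Spectrogram:
    """Complex T x F short-time Fourier transform with two-sided frequency
    axis (Doppler sign is meaningful for approaching/receding motion)."""

    values: np.ndarray  # frames x freqs, complex
    times: np.ndarray
    freqs: np.ndarray
    window: str
    window_len: int
    hop: int

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class FreqDensity:
    """Per-component frequency probability density (sums to one)."""

    probs: np.ndarray
    component_id: int = -1


@dataclass
class SearchResult:
    center_ids: tuple[int, int, int]
    total_distance: float
    assignment: dict[int, int]
    roles: dict[str, int]
    amplitudes: np.ndarray
    distance_trace: np.ndarray | None = None

    @property
    def torso_id(self) -> int:
        return self.roles["torso"]

    @property
    def feet_id(self) -> int:
        return self.roles["feet"]

    @property
    def torso_amplitude(self) -> float:
        return float(self.amplitudes[self.roles["torso"]])


def stft(
    x: np.ndarray,
    window_len: int = 128,
    hop: int | None = None,
    fft_len: int | None = None,
    sample_interval: float = 1.0,
) -> Spectrogram:
    """Hamming-window short-time Fourier transform of a complex sequence.

    The full two-sided frequency axis is retained and fftshifted to ascending
    order.  ``hop`` defaults to a quarter window, ``fft_len`` to the window
    length.
    """
    x = np.asarray(x)
    if window_len > x.size:
        raise ValueError("window longer than the signal")
    hop = window_len // 4 if hop is None else int(hop)
    if hop <= 0:
        raise ValueError("hop must be positive")
    fft_len = window_len if fft_len is None else int(fft_len)
    win = hamming(window_len, sym=False)
    # frames fully inside the signal (no zero-padded edges), centered stamps
    frames = np.lib.stride_tricks.sliding_window_view(x, window_len)[::hop]
    vals = np.fft.fftshift(np.fft.fft(frames * win, n=fft_len, axis=1), axes=1)
    freqs = np.fft.fftshift(np.fft.fftfreq(fft_len, d=sample_interval))
    times = (np.arange(frames.shape[0]) * hop + window_len / 2) * sample_interval
    return Spectrogram(
        values=vals,
        times=times,
        freqs=freqs,
        window="hamming",
        window_len=window_len,
        hop=hop,
    )


def freq_density(sp: Spectrogram, component_id: int = -1) -> FreqDensity:
    """Time-averaged frequency probability density of a spectrogram.

    Each frame's magnitude spectrum is normalized to unit sum (a per-frame
    probability over frequency bins); frames are then averaged and the result
    renormalized.  All-zero frames are skipped with a warning.
    """
    mag = sp.magnitude
    if not np.any(mag):
        raise ValueError("all-zero spectrogram has no frequency density")
    sums = mag.sum(axis=1)
    ok = sums > 0
    if not np.all(ok):
        warnings.warn("skipping all-zero spectrogram frames", stacklevel=2)
    probs = (mag[ok] / sums[ok, None]).mean(axis=0)
    probs = probs / probs.sum()
    return FreqDensity(probs=probs, component_id=component_id)


def _component_densities(
    components: np.ndarray,
    sample_interval: float,
    window_len: int = 128,
    hop: int | None = None,
) -> list[FreqDensity]:
    out = []
    for j, row in enumerate(components):
        sp = stft(row, window_len=window_len, hop=hop, sample_interval=sample_interval)
        out.append(freq_density(sp, component_id=j))
    return out


def search_centers(
    densities: list[FreqDensity],
    amplitudes: np.ndarray,
    keep_trace: bool = False,
    n_significant: int | None = None,
) -> SearchResult:
    """Exhaustive 3-center search over component frequency densities.

    Enumerates every unordered triple of components as candidate centers; the
    cost of a triple is the sum over the remaining components of their
    Euclidean distance to the nearest center.  Ties are broken toward the
    lexicographically smallest index triple.  Among the winning centers the
    largest-amplitude one is labelled torso, the smallest feet, the third
    "other".

    ``n_significant`` guards the feet label: components ranked beyond it
    (e.g. past the knee point of the covariance eigenvalue spectrum, where
    whitening only amplifies an empty band) cannot represent a body part, so
    the feet role goes to the smallest-amplitude center *within* the
    significant set; without eligible candidates the literal smallest-center
    rule applies.
    """
    m = len(densities)
    if m < 4:
        raise ValueError("need at least 4 components to pick 3 centers")
    if m > MAX_SEARCH_COMPONENTS:
        raise ValueError(
            f"exhaustive C(M,3) search capped at M={MAX_SEARCH_COMPONENTS}"
        )
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (m,):
        raise ValueError("need one amplitude per component")

    p = np.stack([d.probs for d in densities])
    diff = p[:, None, :] - p[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    triples = np.array(list(combinations(range(m), 3)))
    # cost per triple: sum over non-center components of min distance to centers
    d3 = dist[:, triples]  # (m, T, 3)
    dmin = d3.min(axis=2)  # (m, T)
    member = np.zeros((m, len(triples)), dtype=bool)
    for c in range(3):
        member[triples[:, c], np.arange(len(triples))] = True
    costs = np.where(member, 0.0, dmin).sum(axis=0)

    best = int(np.argmin(costs))  # combinations() order is lexicographic
    center_ids = tuple(int(i) for i in triples[best])
    nearest = np.array(center_ids)[np.argmin(dist[:, list(center_ids)], axis=1)]
    assignment = {i: int(nearest[i]) for i in range(m)}
    for cid in center_ids:
        assignment[cid] = cid

    order = sorted(center_ids, key=lambda i: amplitudes[i], reverse=True)
    roles = {"torso": order[0], "other": order[1], "feet": order[2]}
    if n_significant is not None:
        eligible = [i for i in order[1:] if i < n_significant]
        if eligible:
            feet = min(eligible, key=lambda i: amplitudes[i])
            other = next(i for i in order[1:] if i != feet)
            roles = {"torso": order[0], "other": other, "feet": feet}
    return SearchResult(
        center_ids=center_ids,
        total_distance=float(costs[best]),
        assignment=assignment,
        roles=roles,
        amplitudes=amplitudes,
        distance_trace=costs if keep_trace else None,
    )
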