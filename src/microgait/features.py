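"""Physical gait features from torso and feet time-velocity tracks.

Five features describe a walker: the torso echo amplitude, the walking cycle,
the maximum torso and feet radial speeds, and the stride length obtained by
integrating a velocity track over one cycle (halved for the feet track, which
contains both feet's swings per cycle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import find_peaks

from .ssm import VelocityTrack

__all__ = [
    "GaitFeatures",
    "max_speed",
    "walking_cycle",
    "peak_clusters",
    "stride_length",
    "extract_all",
]


@dataclass
class GaitFeatures:
    """The five gait features (amplitude excluded from classification by
    default: it depends on clothing/season in real measurements)."""

    torso_amplitude: float
    cycle: float
    max_torso_speed: float
    max_feet_speed: float
    stride_torso: float
    stride_feet: float

    def as_vector(self, include_amplitude: bool = False) -> np.ndarray:
        v = [self.cycle, self.max_torso_speed, self.max_feet_speed, self.stride_torso]
        if include_amplitude:
            v = [self.torso_amplitude] + v
        return np.array(v)

    def __post_init__(self) -> None:
        for name in ("torso_amplitude", "cycle", "max_torso_speed", "max_feet_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for s in (self.stride_torso, self.stride_feet):
            if not 0.1 <= s <= 2.5:
                warnings.warn(
                    f"stride {s:.3f} m outside the 0.1-2.5 m sanity band",
                    stacklevel=2,
                )


def max_speed(track: VelocityTrack) -> float:
    """Maximum radial speed |v| of a track [m/s]."""
    if len(track) == 0:
        raise ValueError("empty track")
    return float(np.max(np.abs(track.velocities)))


def peak_clusters(
    track: VelocityTrack, speed_band: float = 0.2
) -> tuple[float, float, float]:
    """Mean timestamps of the two dominant speed-peak clusters and their
    interval.

    Local maxima separated by at least a quarter of the track duration are
    candidates; the two tallest adjacent ones are kept.  Around each peak the
    contiguous run of samples whose speed lies within ``speed_band`` m/s of
    the peak speed is averaged in time, which stabilizes the peak location
    when the maximum itself is flat or ragged.
    """
    sp = track.speeds
    min_dist = max(1, int(0.25 * sp.size))
    idx, _ = find_peaks(sp, distance=min_dist)
    if idx.size < 2:
        raise ValueError(
            f"found {idx.size} dominant peak(s); need two to estimate the cycle"
        )
    if idx.size > 2:
        # keep the adjacent pair with the largest combined height
        pair = int(np.argmax(sp[idx[:-1]] + sp[idx[1:]]))
        idx = idx[pair : pair + 2]

    centers = []
    for pk in idx:
        lo = pk
        while lo > 0 and sp[lo - 1] >= sp[pk] - speed_band:
            lo -= 1
        hi = pk
        while hi < sp.size - 1 and sp[hi + 1] >= sp[pk] - speed_band:
            hi += 1
        centers.append(float(np.mean(track.times[lo : hi + 1])))
    t1, t2 = centers
    if t2 - t1 <= 0:
        raise ValueError(
            "peak clusters are indistinguishable; narrow the speed band"
        )
    return t1, t2, t2 - t1


def walking_cycle(
    track: VelocityTrack,
    speed_band: float = 0.2,
    convention: str = "paper",
) -> float:
    """Walking-cycle duration [s] from the two dominant peak clusters.

    Both the torso oscillation and the two-feet swing envelope peak twice per
    gait cycle, so the cluster interval is half a cycle; the default 'paper'
    convention doubles it.  'interval' reports the raw interval, 'half' the
    literal halved reading.
    """
    _, _, interval = peak_clusters(track, speed_band)
    if convention == "paper":
        return 2.0 * interval
    if convention == "interval":
        return interval
    if convention == "half":
        return interval / 2.0
    raise ValueError("convention must be 'paper', 'interval' or 'half'")


def stride_length(
    track: VelocityTrack,
    role: str = "torso",
    speed_band: float = 0.2,
    cycle: float | None = None,
) -> float:
    """Stride length [m]: trapezoidal integral of speed over one cycle.

    The integration window spans one cycle centered on the two peak clusters.
    For the feet track the integral is halved, since it contains both feet's
    swing advances per cycle.
    """
    if role not in ("torso", "feet"):
        raise ValueError("role must be 'torso' or 'feet'")
    t1, t2, interval = peak_clusters(track, speed_band)
    if cycle is None:
        cycle = 2.0 * interval
    # one-cycle window centered on the two peak clusters, shifted (not
    # truncated) when it would run past the ends of the track
    lo, hi = t1 - (cycle - interval) / 2, t2 + (cycle - interval) / 2
    t0, t_end = float(track.times[0]), float(track.times[-1])
    if hi > t_end:
        hi = t_end
        lo = hi - cycle
    if lo < t0:
        lo = t0
        hi = min(lo + cycle, t_end)
    m = (track.times >= lo) & (track.times <= hi)
    if m.sum() < 2:
        raise ValueError("cycle window contains too few track samples")
    s = trapezoid(track.speeds[m], track.times[m])
    return float(s / 2.0 if role == "feet" else s)


def extract_all(
    torso_track: VelocityTrack,
    feet_track: VelocityTrack,
    torso_component_amplitude: float,
    speed_band: float = 0.2,
    cycle_convention: str = "paper",
    cycle_source: str = "feet",
) -> GaitFeatures:
    """Assemble the five gait features from the two tracks.

    The cycle is taken from the feet track by default (its swing peaks are
    sharper than the torso oscillation, giving the smaller period error);
    ``cycle_source='torso'`` switches curves.
    """
    if len(torso_track) == 0 or len(feet_track) == 0:
        raise ValueError("empty track")
    if np.max(np.abs(torso_track.velocities)) <= 0 or np.max(np.abs(feet_track.velocities)) <= 0:
        raise ValueError("zero-velocity track")
    src = feet_track if cycle_source == "feet" else torso_track
    cyc = walking_cycle(src, speed_band, cycle_convention)
    return GaitFeatures(
        torso_amplitude=float(torso_component_amplitude),
        cycle=cyc,
        max_torso_speed=max_speed(torso_track),
        max_feet_speed=max_speed(feet_track),
        stride_torso=stride_length(torso_track, "torso", speed_band, cycle=cyc),
        stride_feet=stride_length(feet_track, "feet", speed_band, cycle=cyc),
    )
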