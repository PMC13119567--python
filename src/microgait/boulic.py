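"""Walking-human radar echo simulation based on the Boulic kinematic model.

The Boulic model is a parameterized description of human walking derived from
biomechanical measurements: given a subject's height and average walking speed
it prescribes the gait cycle, the support (stance) duration, the periodic
pelvis translations and the limb trajectories.  Here the body is reduced to 16
segment scatterers (head, shoulders, arms, torso, hips, legs, feet), each an
ellipsoid whose radar cross-section weights its contribution to the complex
slow-time echo

    s(t_k) = sum_i sigma_i * exp(-j * 4 * pi * f * r_i(t_k) / c)

with ``r_i`` the radar-to-scatterer distance and ``f`` the carrier frequency.
The same kinematics also provide ground-truth gait features (peak torso and
feet radial speeds, walking cycle, stride length) so that echo-domain feature
extraction can be scored against the model itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import c as C_LIGHT

__all__ = [
    "Ellipsoid",
    "WalkParams",
    "SegmentTrajectory",
    "Echo",
    "BODY_SEGMENTS",
    "ellipsoid_rcs",
    "segment_rcs_table",
    "gait_timing",
    "boulic_trajectories",
    "synthesize_echo",
    "ground_truth_features",
    "simulate_walk",
]

#: Height-normalization constant of the cycle relation Rc = 1.346 * sqrt(vr),
#: vr = v / (CYCLE_NORM * height).  Calibrated once so that a 1.70 m subject
#: walking at 0.7 m/s has a 1.07 s walking cycle; fixed thereafter.
CYCLE_NORM = 0.2602115

#: Spatial scale of the Boulic relative amplitudes: the thigh height,
#: expressed as a fraction of standing height.
THIGH_HEIGHT_FRAC = 0.53

# Anthropometric landmark heights / widths as fractions of standing height.
_HEAD_Z = 0.93
_SHOULDER_Z = 0.818
_SHOULDER_HW = 0.129
_ELBOW_Z = 0.63
_WRIST_Z = 0.485
_TORSO_Z = 0.674
_HIP_Z = 0.53
_KNEE_Z = 0.285
_ANKLE_Z = 0.039
_HIP_HW = 0.053  # half distance between hip joints
_FOOT_LEN = 0.152


@dataclass(frozen=True)
class Ellipsoid:
    """Body-segment scatterer: an ellipsoid with semi-axes ``a, b, c`` [m]
    observed at incident angle ``theta`` and azimuth ``phi`` [rad]."""

    name: str
    a: float
    b: float
    c: float
    theta: float = math.pi / 2
    phi: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"{self.name}: semi-axes must be positive")
        if not 0.0 <= self.theta <= math.pi:
            raise ValueError(f"{self.name}: theta outside [0, pi]")
        if not -math.pi <= self.phi <= math.pi:
            raise ValueError(f"{self.name}: phi outside [-pi, pi]")


def ellipsoid_rcs(e: Ellipsoid) -> float:
    """Radar cross-section [m^2] of an ellipsoid.

    RCS = pi a^2 b^2 c^2 / (a^2 sin^2(th) cos^2(ph) + b^2 sin^2(th) sin^2(ph)
    + c^2 cos^2(th))^2.  Strictly positive for valid semi-axes.
    """
    st, ct = math.sin(e.theta), math.cos(e.theta)
    sp, cp = math.sin(e.phi), math.cos(e.phi)
    denom = e.a**2 * st**2 * cp**2 + e.b**2 * st**2 * sp**2 + e.c**2 * ct**2
    if denom <= 0:  # impossible for a non-degenerate ellipsoid
        raise ValueError("degenerate ellipsoid orientation")
    return math.pi * e.a**2 * e.b**2 * e.c**2 / denom**2


#: The 16 body segments with their ellipsoid semi-axes [m] at normal incidence
#: (theta=90 deg, phi=0 deg).  Dimensions refer to a ~1.70 m subject.
BODY_SEGMENTS: tuple[Ellipsoid, ...] = (
    Ellipsoid("Head", 0.15, 0.15, 0.20),
    Ellipsoid("Right Shoulder", 0.08, 0.08, 0.10),
    Ellipsoid("Left Shoulder", 0.08, 0.08, 0.10),
    Ellipsoid("Right Upper Arm", 0.06, 0.06, 0.30),
    Ellipsoid("Left Upper Arm", 0.06, 0.06, 0.30),
    Ellipsoid("Right Lower Arm", 0.05, 0.05, 0.25),
    Ellipsoid("Left Lower Arm", 0.05, 0.05, 0.25),
    Ellipsoid("Torso", 0.40, 0.25, 0.50),
    Ellipsoid("Right Hip", 0.10, 0.10, 0.12),
    Ellipsoid("Left Hip", 0.10, 0.10, 0.12),
    Ellipsoid("Right Upper Leg", 0.20, 0.08, 0.40),
    Ellipsoid("Left Upper Leg", 0.20, 0.08, 0.40),
    Ellipsoid("Left Lower Leg", 0.15, 0.06, 0.35),
    Ellipsoid("Right Lower Leg", 0.15, 0.06, 0.35),
    Ellipsoid("Left Foot", 0.10, 0.05, 0.15),
    Ellipsoid("Right Foot", 0.10, 0.05, 0.15),
)

SEGMENT_NAMES = tuple(e.name for e in BODY_SEGMENTS)
_BY_NAME = {e.name: e for e in BODY_SEGMENTS}


def _segment(name: str) -> Ellipsoid:
    return _BY_NAME[name]


def segment_rcs_table(height: float = 1.70) -> dict[str, float]:
    """RCS [m^2] per segment.  Semi-axes scale linearly with height/1.70 so
    that taller subjects present a larger cross-section (RCS ~ scale^4)."""
    s = height / 1.70
    out = {}
    for e in BODY_SEGMENTS:
        out[e.name] = ellipsoid_rcs(replace(e, a=e.a * s, b=e.b * s, c=e.c * s))
    return out


@dataclass
class WalkParams:
    """Simulation configuration.

    height [m], velocity [m/s]: the two Boulic inputs.
    carrier_freq [Hz], sample_interval [s]: radar carrier and slow-time step.
    duration [s]: simulated span; ``None`` picks 1.25 gait cycles so that a
    full cycle survives the sliding-window truncation of the tracker.
    initial_range [m]: starting radar-subject distance along the line of sight.
    radar_height [m]: radar elevation above ground.
    snr_db: receiver signal-to-noise ratio (total echo power over complex
    white noise power); ``None`` (default) keeps the simulation noise-free —
    the feet return sits some 50 dB below the torso in echo power, so any
    appreciable receiver noise buries exactly the subspace the feet tracker
    needs.
    amplitude_mode: 'sqrt_rcs' (default) weights each segment by the physical
    field amplitude sqrt(sigma_i); 'rcs' uses sigma_i directly.
    rcs_mode: 'oriented' modulates each sigma_i with the segment's
    instantaneous attitude (limbs off broadside return far less); 'table'
    keeps the fixed broadside values.
    """

    height: float = 1.70
    velocity: float = 0.7
    carrier_freq: float = 15e9
    sample_interval: float = 1.0 / 2000.0
    duration: float | None = None
    initial_range: float = 5.0
    radar_height: float = 1.0
    snr_db: float | None = None
    seed: int = 0
    amplitude_mode: str = "sqrt_rcs"
    rcs_mode: str = "oriented"
    foot_clearance: float = 0.03

    def __post_init__(self) -> None:
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.amplitude_mode not in ("rcs", "sqrt_rcs"):
            raise ValueError("amplitude_mode must be 'rcs' or 'sqrt_rcs'")
        if self.rcs_mode not in ("oriented", "table"):
            raise ValueError("rcs_mode must be 'oriented' or 'table'")
        if not 0.1 <= self.velocity <= 3.0:
            warnings.warn(
                "walking velocity outside the validated range of the Boulic "
                "model (0.1-3.0 m/s); kinematics are extrapolated",
                stacklevel=2,
            )
        tc, ds = gait_timing(self.height, self.velocity)
        if self.duration is None:
            self.duration = 1.25 * tc
        if self.duration < tc:
            warnings.warn("duration covers less than one gait cycle", stacklevel=2)
        # Nyquist guard: predicted peak foot Doppler must stay below half the PRF.
        v_feet = 2.0 * self.velocity * tc / max(tc - ds, 1e-6) + 0.5
        if 2 * v_feet * self.carrier_freq / C_LIGHT >= 0.5 / self.sample_interval:
            raise ValueError(
                "sample_interval too large: predicted feet Doppler exceeds Nyquist"
            )

    @property
    def cycle(self) -> float:
        """Walking-cycle duration Tc [s]."""
        return gait_timing(self.height, self.velocity)[0]

    @property
    def relative_velocity(self) -> float:
        return self.velocity / (CYCLE_NORM * self.height)


@dataclass
class SegmentTrajectory:
    """Radar-relative trajectory of one body segment.

    ``velocities`` uses the approach-positive convention: positive when the
    scatterer closes on the radar (-dr/dt).
    """

    segment: str
    times: np.ndarray
    ranges: np.ndarray
    velocities: np.ndarray = field(default=None)  # type: ignore[assignment]
    positions: np.ndarray | None = None
    #: unit long-axis (c-axis) direction of the segment ellipsoid per sample
    axes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.velocities is None:
            dt = float(self.times[1] - self.times[0])
            self.velocities = -np.gradient(self.ranges, dt)


@dataclass
class Echo:
    """Complex slow-time echo sequence."""

    samples: np.ndarray
    sample_interval: float
    carrier_freq: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.size < 2:
            raise ValueError("echo must have at least two samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("echo contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sample_interval


def gait_timing(height: float, velocity: float) -> tuple[float, float]:
    """Cycle duration Tc and support (stance) duration Ds, both in seconds.

    Tc = 1.346 / sqrt(vr) with the calibrated relative velocity
    vr = v / (CYCLE_NORM * height); Ds = 0.752 * Tc - 0.143 (clamped to a
    physically meaningful 50-85% duty cycle).
    """
    vr = velocity / (CYCLE_NORM * height)
    tc = 1.346 / math.sqrt(vr)
    ds = 0.752 * tc - 0.143
    ds = min(max(ds, 0.50 * tc), 0.85 * tc)
    return tc, ds


def _pelvis_translations(t: np.ndarray, tc: float, vr: float, scale: float):
    """Boulic periodic pelvis translations [m]: (forward, lateral, vertical).

    Amplitudes are relative (fractions of the thigh height ``scale``); forward
    and vertical oscillate at twice the gait frequency, lateral at the gait
    frequency.
    """
    ph = t / tc
    a_v = 0.015 * vr
    tv = scale * (-a_v + a_v * np.sin(2 * np.pi * (2 * ph - 0.35)))
    a_l = -0.032 if vr > 0.5 else -0.128 * vr**2 + 0.128 * vr
    tl = scale * a_l * np.sin(2 * np.pi * (ph - 0.1))
    a_f = -0.021 if vr > 0.5 else -0.084 * vr**2 + 0.084 * vr
    phi_f = 0.625 - 0.037 * vr
    tf = scale * a_f * np.sin(2 * np.pi * (2 * ph + 2 * phi_f))
    return tf, tl, tv


def _ankle_forward(t: np.ndarray, tc: float, ds: float, v: float, shift: float):
    """World forward position [m] of one ankle (leg with heel strike at
    cycle phase ``shift``), plus the swing-phase fraction tau (nan in stance).

    During stance the ankle is fixed on the ground; during swing it advances
    by one cycle length with a cycloidal (1 - cos) velocity profile, which is
    smooth at both ends and peaks at twice the mean swing speed.
    """
    lc = v * tc
    u = t / tc + shift
    k = np.floor(u)
    frac = u - k
    ds_frac = ds / tc
    # ankle position during stance k: body position at heel strike + half the
    # stance advance (the hip passes over the ankle at mid-stance)
    contact = (k - shift) * tc * v + v * ds / 2.0
    swing = frac >= ds_frac
    tau = np.where(swing, (frac - ds_frac) / (1.0 - ds_frac), np.nan)
    adv = np.where(swing, lc * (tau - np.sin(2 * np.pi * tau) / (2 * np.pi)), 0.0)
    return contact + np.nan_to_num(adv), tau


def boulic_trajectories(p: WalkParams) -> dict[str, SegmentTrajectory]:
    """Per-segment radar range/velocity trajectories for a walking subject.

    The subject starts ``initial_range`` metres from the radar on the line of
    sight and walks straight toward it; the radar sits at the origin at
    ``radar_height``.  Returns a dict keyed by segment name.
    """
    h = p.height
    tc, ds = gait_timing(h, p.velocity)
    vr = p.relative_velocity
    scale = THIGH_HEIGHT_FRAC * h

    n = int(round(p.duration / p.sample_interval))
    t = np.arange(n) * p.sample_interval

    tf, tl, tv = _pelvis_translations(t, tc, vr, scale)
    fwd = p.velocity * t + tf  # forward distance travelled (toward the radar)

    thigh = (_HIP_Z - _KNEE_Z) * h
    shank = (_KNEE_Z - _ANKLE_Z) * h
    leg = thigh + shank
    ankle_h = _ANKLE_Z * h

    # pelvis / shoulder yaw (counter-rotation); small fore-aft offsets of the
    # hip and shoulder scatterers
    ph_r = t / tc  # right-leg phase (heel strike at 0)
    yaw_p = math.radians(4.0) * np.cos(2 * np.pi * (ph_r - 0.3))
    yaw_s = -math.radians(5.0) * np.cos(2 * np.pi * (ph_r - 0.3))

    pos: dict[str, np.ndarray] = {}
    axes: dict[str, np.ndarray] = {}
    vertical = np.broadcast_to(np.array([0.0, 0.0, 1.0]), (n, 3))

    def world(forward, lateral, height_z):
        """Stack world coordinates: x decreases as the subject approaches."""
        return np.stack(
            [p.initial_range - forward, np.broadcast_to(lateral, t.shape), height_z],
            axis=-1,
        )

    def sagittal_axis(dfwd, dz):
        """Unit world vector from a (forward, up) sagittal direction."""
        a = np.stack([-np.broadcast_to(dfwd, t.shape), np.zeros(n), np.broadcast_to(dz, t.shape)], axis=-1)
        return a / (np.linalg.norm(a, axis=-1, keepdims=True) + 1e-300)

    pos["Head"] = world(fwd, tl, _HEAD_Z * h + tv)
    pos["Torso"] = world(fwd, tl, _TORSO_Z * h + tv)
    axes["Head"] = vertical
    axes["Torso"] = vertical

    shw = _SHOULDER_HW * h
    for side, sgn in (("Right", +1), ("Left", -1)):
        off = -sgn * shw * np.sin(yaw_s)
        pos[f"{side} Shoulder"] = world(fwd + off, tl + sgn * shw, _SHOULDER_Z * h + tv)
        axes[f"{side} Shoulder"] = vertical

    # arms: swing in phase with the contralateral leg; the swing amplitude
    # grows with the relative velocity and is large enough that the lower arm
    # dwells outside the torso Doppler band at its extremes
    lua = (_SHOULDER_Z - _ELBOW_Z) * h
    lla = (_ELBOW_Z - _WRIST_Z) * h
    a_arm = min(0.6, 0.35 * vr)
    elbow0 = math.radians(15.0)
    for side, sgn, arm_shift in (("Right", +1, 0.5), ("Left", -1, 0.0)):
        beta = a_arm * np.cos(2 * np.pi * (ph_r + arm_shift))
        sh_fwd = fwd - sgn * shw * np.sin(yaw_s)
        sh_z = _SHOULDER_Z * h + tv
        el_fwd = sh_fwd + lua * np.sin(beta)
        el_z = sh_z - lua * np.cos(beta)
        # elbow flexes as the arm swings forward
        beta2 = beta + elbow0 + 0.8 * a_arm * (1 + np.cos(2 * np.pi * (ph_r + arm_shift))) / 2
        wr_fwd = el_fwd + lla * np.sin(beta2)
        wr_z = el_z - lla * np.cos(beta2)
        ca = 0.42  # proximal volume centroid, as for the legs
        pos[f"{side} Upper Arm"] = world(
            sh_fwd + ca * (el_fwd - sh_fwd), tl + sgn * shw, sh_z + ca * (el_z - sh_z)
        )
        pos[f"{side} Lower Arm"] = world(
            el_fwd + ca * (wr_fwd - el_fwd), tl + sgn * shw, el_z + ca * (wr_z - el_z)
        )
        axes[f"{side} Upper Arm"] = sagittal_axis(el_fwd - sh_fwd, el_z - sh_z)
        axes[f"{side} Lower Arm"] = sagittal_axis(wr_fwd - el_fwd, wr_z - el_z)

    # legs: prescribed ankle trajectories + two-link inverse kinematics
    hhw = _HIP_HW * h
    for side, sgn, shift in (("Right", +1, 0.0), ("Left", -1, 0.5)):
        hip_fwd = fwd - sgn * hhw * np.sin(yaw_p)
        hip_z = _HIP_Z * h + tv
        hip_y = tl + sgn * hhw
        pos[f"{side} Hip"] = world(hip_fwd, hip_y, hip_z)

        ank_fwd, tau = _ankle_forward(t, tc, ds, p.velocity, shift)
        dx = hip_fwd - ank_fwd  # positive: ankle behind the hip
        # minimum ankle height for leg reachability (straight leg: heel-off /
        # heel-rocker), plus a heel-lift arc peaking in early swing: the heel
        # rises toward the pelvis after toe-off, flexing the knee and letting
        # the shank whip through while the knee itself stays slow
        reach = hip_z - np.sqrt(np.maximum(leg**2 - dx**2, 1e-9))
        tau_c = np.clip(np.nan_to_num(tau), 0.0, 1.0)
        # asymmetric arc peaking in early-mid swing, zero-valued with finite
        # slope at both ends
        g = tau_c + 0.45 * tau_c * (1.0 - tau_c)
        lift = (0.10 + p.foot_clearance) * np.sin(np.pi * g) ** 1.5
        # smooth maximum keeps the leg reachable (d <= thigh + shank) without
        # velocity kinks at the stance/swing transitions
        k = 80.0
        ank_z = np.logaddexp(k * (ankle_h + lift), k * reach) / k

        # knee from two-link IK in the sagittal plane, bending forward
        ddx = ank_fwd - hip_fwd
        ddz = ank_z - hip_z
        d = np.sqrt(ddx**2 + ddz**2)
        d = np.clip(d, abs(thigh - shank) + 1e-9, leg - 1e-9)
        cos_a = (thigh**2 + d**2 - shank**2) / (2 * thigh * d)
        sin_a = np.sqrt(np.clip(1 - cos_a**2, 0.0, 1.0))
        ux, uz = ddx / d, ddz / d
        # perpendicular chosen so the knee moves forward (toward the radar)
        knee_fwd = hip_fwd + thigh * (cos_a * ux - sin_a * uz)
        knee_z = hip_z + thigh * (cos_a * uz + sin_a * ux)

        # scatterers at the segment volume centroids: limb mass concentrates
        # proximally (thigh, calf), so the centroid sits ~42% down the bone
        cl = 0.42
        pos[f"{side} Upper Leg"] = world(
            hip_fwd + cl * (knee_fwd - hip_fwd), hip_y, hip_z + cl * (knee_z - hip_z)
        )
        pos[f"{side} Lower Leg"] = world(
            knee_fwd + cl * (ank_fwd - knee_fwd), hip_y, knee_z + cl * (ank_z - knee_z)
        )
        pos[f"{side} Foot"] = world(
            ank_fwd + 0.35 * _FOOT_LEN * h, hip_y, ank_z - 0.015
        )
        axes[f"{side} Hip"] = vertical
        axes[f"{side} Upper Leg"] = sagittal_axis(knee_fwd - hip_fwd, knee_z - hip_z)
        axes[f"{side} Lower Leg"] = sagittal_axis(ank_fwd - knee_fwd, ank_z - knee_z)
        # foot long axis heel->toe; the toe stays near the ground, so ankle
        # lift (heel-off, swing) pitches the foot nose-down naturally
        lf = _FOOT_LEN * h
        toe_z = np.maximum(0.015, ank_z - 0.12)
        axes[f"{side} Foot"] = sagittal_axis(lf, toe_z - (ank_z - 0.03))

    radar = np.array([0.0, 0.0, p.radar_height])
    out: dict[str, SegmentTrajectory] = {}
    for name in SEGMENT_NAMES:
        r = np.linalg.norm(pos[name] - radar, axis=-1)
        out[name] = SegmentTrajectory(name, t, r, positions=pos[name], axes=axes[name])
    return out


def oriented_sigma(
    tr: SegmentTrajectory, e: Ellipsoid, radar: np.ndarray
) -> np.ndarray:
    """Per-sample RCS of a segment whose long (c) axis follows the limb.

    The incidence angle is taken between the radar line of sight and the
    segment axis; the azimuth stays in the sagittal plane (phi = 0), so the
    ``a`` semi-axis is the transverse one facing the radar.  For upright
    segments this reduces to the broadside (theta = 90 deg) reference values.
    """
    if tr.positions is None or tr.axes is None:
        raise ValueError("trajectory lacks positions/axes")
    los = radar - tr.positions
    los = los / np.linalg.norm(los, axis=-1, keepdims=True)
    cos2 = np.sum(los * tr.axes, axis=-1) ** 2
    sin2 = 1.0 - cos2
    denom = e.a**2 * sin2 + e.c**2 * cos2
    return math.pi * e.a**2 * e.b**2 * e.c**2 / denom**2


def synthesize_echo(
    trajs: dict[str, SegmentTrajectory],
    rcs: dict[str, float],
    p: WalkParams,
) -> Echo:
    """Sum the per-segment complex returns into one slow-time echo.

    Each segment contributes amplitude sigma_i (or sqrt(sigma_i)) with phase
    -4*pi*f*r_i(t)/c.  Under ``rcs_mode='oriented'`` sigma_i varies with the
    segment's instantaneous orientation (limbs tilted away from broadside
    return far less); ``'table'`` uses the fixed broadside values.  Optional
    complex white receiver noise at ``snr_db``.
    """
    lengths = {len(tr.ranges) for tr in trajs.values()}
    if len(lengths) != 1:
        raise ValueError("segment trajectories have mismatched lengths")
    n = lengths.pop()
    s = np.zeros(n, dtype=np.complex128)
    radar = np.array([0.0, 0.0, p.radar_height])
    scale = None
    for name, tr in trajs.items():
        if p.rcs_mode == "oriented" and tr.axes is not None:
            if scale is None:
                # recover the height scale from the broadside table
                base = ellipsoid_rcs(_segment(name))
                scale = math.sqrt(math.sqrt(rcs[name] / base))
            e0 = _segment(name)
            e = replace(e0, a=e0.a * scale, b=e0.b * scale, c=e0.c * scale)
            sigma = oriented_sigma(tr, e, radar)
        else:
            sigma = rcs[name]
        amp = sigma if p.amplitude_mode == "rcs" else np.sqrt(sigma)
        s += amp * np.exp(-4j * np.pi * p.carrier_freq * tr.ranges / C_LIGHT)
    if p.snr_db is not None:
        rng = np.random.default_rng(p.seed)
        pwr = float(np.mean(np.abs(s) ** 2))
        npwr = pwr / 10 ** (p.snr_db / 10)
        s = s + np.sqrt(npwr / 2) * (
            rng.standard_normal(n) + 1j * rng.standard_normal(n)
        )
    return Echo(s, p.sample_interval, p.carrier_freq)


def ground_truth_features(
    trajs: dict[str, SegmentTrajectory], p: WalkParams
) -> dict[str, float]:
    """Reference gait features straight from the kinematics (not the echo).

    Returns max torso / feet radial speeds [m/s], walking cycle [s], stride
    length [m] (distance advanced per cycle, = v * Tc) and the torso echo
    amplitude (the torso RCS weight under the configured amplitude mode).
    """
    tc, _ = gait_timing(p.height, p.velocity)
    torso = trajs["Torso"]
    feet = np.maximum(
        np.abs(trajs["Left Foot"].velocities), np.abs(trajs["Right Foot"].velocities)
    )
    sigma = segment_rcs_table(p.height)["Torso"]
    amp = sigma if p.amplitude_mode == "rcs" else math.sqrt(sigma)
    return {
        "max_torso_speed": float(np.max(np.abs(torso.velocities))),
        "max_feet_speed": float(np.max(feet)),
        "cycle": tc,
        "stride": p.velocity * tc,
        "torso_amplitude": amp,
    }


def simulate_walk(p: WalkParams):
    """Convenience: trajectories, echo and ground-truth features in one call."""
    trajs = boulic_trajectories(p)
    echo = synthesize_echo(trajs, segment_rcs_table(p.height), p)
    gt = ground_truth_features(trajs, p)
    return echo, trajs, gt
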