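"""Boulic simulator: RCS model, gait timing, kinematic ground truth, echo."""

import math

import numpy as np
import pytest
from scipy.constants import c as C_LIGHT

from microgait.boulic import (
    BODY_SEGMENTS,
    Ellipsoid,
    WalkParams,
    boulic_trajectories,
    ellipsoid_rcs,
    gait_timing,
    ground_truth_features,
    oriented_sigma,
    segment_rcs_table,
    simulate_walk,
    synthesize_echo,
)

# published broadside RCS of the 16 segments: (sigma [m^2], dBsm)
RCS_TABLE = {
    "Head": (0.1257, -9.0),
    "Right Shoulder": (0.0314, -15.0),
    "Left Shoulder": (0.0314, -15.0),
    "Right Upper Arm": (0.2827, -5.5),
    "Left Upper Arm": (0.2827, -5.5),
    "Right Lower Arm": (0.1963, -7.1),
    "Left Lower Arm": (0.1963, -7.1),
    "Torso": (0.3068, -5.1),
    "Right Hip": (0.0452, -13.4),
    "Left Hip": (0.0452, -13.4),
    "Right Upper Leg": (0.0804, -10.9),
    "Left Upper Leg": (0.0804, -10.9),
    "Left Lower Leg": (0.0616, -12.1),
    "Right Lower Leg": (0.0616, -12.1),
    "Left Foot": (0.0177, -17.5),
    "Right Foot": (0.0177, -17.5),
}


@pytest.mark.parametrize("seg", BODY_SEGMENTS, ids=lambda e: e.name)
def test_rcs_reference_values(seg):
    """Broadside ellipsoid RCS matches the published table to 4 decimals and
    the dBsm column to 0.05 dB."""
    sigma, dbsm = RCS_TABLE[seg.name]
    val = ellipsoid_rcs(seg)
    assert abs(val - sigma) < 5e-5
    assert abs(10 * math.log10(val) - dbsm) < 0.05


def test_rcs_sphere_reduces_to_cross_section():
    for theta, phi in ((0.3, -1.0), (1.2, 0.5), (math.pi / 2, 0.0)):
        e = Ellipsoid("s", 0.2, 0.2, 0.2, theta, phi)
        assert ellipsoid_rcs(e) == pytest.approx(math.pi * 0.2**2, rel=1e-12)


def test_ellipsoid_validation():
    with pytest.raises(ValueError):
        Ellipsoid("bad", -0.1, 0.1, 0.1)
    with pytest.raises(ValueError):
        Ellipsoid("bad", 0.1, 0.1, 0.1, theta=4.0)


def test_rcs_table_scales_with_height():
    small, tall = segment_rcs_table(1.60), segment_rcs_table(1.80)
    assert all(tall[k] > small[k] for k in small)


def test_ground_truth_matches_published_features(default_model):
    """(1.70 m, 0.7 m/s): torso peak 0.92 m/s, feet peak 3.59 m/s, cycle
    1.07 s, stride 0.74 m, each within 5%."""
    gt = default_model.ground_truth
    assert gt["max_torso_speed"] == pytest.approx(0.92, rel=0.05)
    assert gt["max_feet_speed"] == pytest.approx(3.59, rel=0.05)
    assert gt["cycle"] == pytest.approx(1.07, rel=0.05)
    assert gt["stride"] == pytest.approx(0.74, rel=0.05)


def test_stride_is_speed_times_cycle(default_model):
    gt = default_model.ground_truth
    assert gt["stride"] == pytest.approx(0.7 * gt["cycle"], rel=1e-9)


def test_cycle_shortens_for_faster_taller_normalization():
    tc_slow, _ = gait_timing(1.70, 0.5)
    tc_fast, _ = gait_timing(1.70, 1.2)
    assert tc_fast < tc_slow


def test_torso_approaches_radar_on_average(default_model):
    r = default_model.trajectories["Torso"].ranges
    n = r.size
    assert r[-1] < r[0]
    # windowed means decrease monotonically
    w = np.array_split(r, 8)
    means = [x.mean() for x in w]
    assert all(a > b for a, b in zip(means, means[1:]))


def test_left_right_symmetry_half_cycle_shift(default_model):
    """Symmetric segments trace the same velocity curve shifted by half a
    gait cycle."""
    p = default_model.params
    shift = int(round(p.cycle / 2 / p.sample_interval))
    for name in ("Foot", "Lower Leg", "Upper Arm"):
        vl = default_model.trajectories[f"Left {name}"].velocities
        vr = default_model.trajectories[f"Right {name}"].velocities
        a, b = vl[shift:], vr[: vr.size - shift]
        err = np.max(np.abs(a - b)) / np.max(np.abs(vr))
        assert err < 0.05, name


def test_torso_oscillates_at_twice_gait_frequency():
    p = WalkParams(duration=4.28)  # four gait cycles resolve the line
    v = boulic_trajectories(p)["Torso"].velocities
    v = v - v.mean()
    spec = np.abs(np.fft.rfft(v * np.hanning(v.size)))
    freqs = np.fft.rfftfreq(v.size, p.sample_interval)
    f_peak = freqs[np.argmax(spec)]
    assert f_peak == pytest.approx(2.0 / p.cycle, rel=0.15)


def test_feet_velocity_periodic_at_gait_cycle():
    p = WalkParams(duration=3.21)  # three gait cycles
    v = np.abs(boulic_trajectories(p)["Left Foot"].velocities)
    v = v - v.mean()
    lag = int(round(p.cycle / p.sample_interval))
    ac = np.correlate(v, v, "full")[v.size - 1 :]
    # autocorrelation peak (away from zero lag) sits at the cycle lag
    search = ac[lag // 2 : 3 * lag // 2]
    assert abs((np.argmax(search) + lag // 2) - lag) <= int(0.03 * lag)


def test_fastest_segment_at_first_peak_is_the_foot(default_model):
    trajs = default_model.trajectories
    lf = np.abs(trajs["Left Foot"].velocities)
    pk = np.argmax(lf[: int(0.6 * lf.size)])
    speeds = {n: abs(t.velocities[pk]) for n, t in trajs.items()}
    assert max(speeds, key=speeds.get) == "Left Foot"
    assert speeds["Left Shoulder"] < speeds["Torso"] + 0.25


def test_static_scatterer_gives_constant_phase():
    p = WalkParams(rcs_mode="table")
    trajs = boulic_trajectories(p)
    tr = trajs["Torso"]
    tr.ranges = np.full_like(tr.ranges, 4.0)
    echo = synthesize_echo({"Torso": tr}, {"Torso": 1.0}, p)
    assert np.allclose(echo.samples, echo.samples[0], atol=1e-12)


def test_constant_velocity_scatterer_is_pure_doppler_tone():
    p = WalkParams(rcs_mode="table")
    n = 2000
    t = np.arange(n) * p.sample_interval
    r = 5.0 - 0.8 * t
    from microgait.boulic import SegmentTrajectory

    tr = SegmentTrajectory("Torso", t, r)
    echo = synthesize_echo({"Torso": tr}, {"Torso": 1.0}, p)
    spec = np.abs(np.fft.fft(echo.samples))
    freqs = np.fft.fftfreq(n, p.sample_interval)
    f_peak = freqs[np.argmax(spec)]
    assert f_peak == pytest.approx(2 * 0.8 * p.carrier_freq / C_LIGHT, abs=1.5)


def test_echo_energy_ordering_torso_over_feet(default_model):
    """The torso contributes more echo magnitude than a foot."""
    p = default_model.params
    trajs = default_model.trajectories
    rcs = segment_rcs_table(p.height)
    torso = synthesize_echo({"Torso": trajs["Torso"]}, rcs, p)
    foot = synthesize_echo({"Left Foot": trajs["Left Foot"]}, rcs, p)
    assert np.mean(np.abs(torso.samples)) > 3 * np.mean(np.abs(foot.samples))


def test_oriented_sigma_broadside_matches_table(default_model):
    radar = np.array([0.0, 0.0, 1.0])
    tr = default_model.trajectories["Torso"]
    sig = oriented_sigma(tr, BODY_SEGMENTS[7], radar)
    assert np.allclose(sig, 0.3068, rtol=0.02)


def test_mismatched_lengths_rejected(default_model):
    p = default_model.params
    trajs = dict(default_model.trajectories)
    import copy

    short = copy.copy(trajs["Head"])
    short.ranges = short.ranges[:-10]
    trajs["Head"] = short
    with pytest.raises(ValueError):
        synthesize_echo(trajs, segment_rcs_table(p.height), p)


def test_nyquist_guard_rejects_coarse_sampling():
    with pytest.raises(ValueError):
        WalkParams(sample_interval=1.0 / 300.0)


def test_out_of_range_velocity_warns():
    with pytest.warns(UserWarning):
        WalkParams(velocity=0.05, sample_interval=1.0 / 8000.0)


def test_noise_seed_reproducible():
    p1 = WalkParams(snr_db=25.0, seed=3)
    p2 = WalkParams(snr_db=25.0, seed=3)
    e1, _, _ = simulate_walk(p1)
    e2, _, _ = simulate_walk(p2)
    assert np.array_equal(e1.samples, e2.samples)
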