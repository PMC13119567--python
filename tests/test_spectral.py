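"""Spectrogram, frequency probability densities and the 3-center search."""

from itertools import combinations

import numpy as np
import pytest

from microgait.spectral import FreqDensity, Spectrogram, freq_density, search_centers, stft


def _tone(f, n, dt):
    return np.exp(2j * np.pi * f * np.arange(n) * dt)


def test_stft_tone_concentrates_in_one_bin():
    dt = 1e-3
    sp = stft(_tone(120.0, 1024, dt), window_len=128, sample_interval=dt)
    peak_bins = sp.freqs[np.argmax(sp.magnitude, axis=1)]
    # every frame peaks in the bin nearest the tone (grid step 7.8125 Hz)
    assert np.all(peak_bins == peak_bins[0])
    assert np.all(np.abs(peak_bins - 120.0) <= 7.8125 / 2 + 1e-9)


def test_stft_parseval_per_frame():
    """Per-frame DFT energy equals the windowed signal energy (Parseval)."""
    rng = np.random.default_rng(2)
    x = rng.standard_normal(700) + 1j * rng.standard_normal(700)
    sp = stft(x, window_len=128, hop=32, sample_interval=1e-3)
    from scipy.signal.windows import hamming

    win = hamming(128, sym=False)
    for k in range(sp.values.shape[0]):
        seg = x[k * 32 : k * 32 + 128] * win
        lhs = np.sum(np.abs(sp.values[k]) ** 2) / 128
        assert lhs == pytest.approx(np.sum(np.abs(seg) ** 2), rel=1e-6)


def test_stft_input_validation():
    with pytest.raises(ValueError):
        stft(np.ones(64, dtype=complex), window_len=128)
    with pytest.raises(ValueError):
        stft(np.ones(512, dtype=complex), window_len=128, hop=0)


def test_density_uniform_for_flat_spectrogram():
    sp = Spectrogram(
        values=np.full((5, 16), 2.0 + 0j),
        times=np.arange(5.0),
        freqs=np.arange(16.0),
        window="hamming",
        window_len=16,
        hop=4,
    )
    d = freq_density(sp)
    assert np.allclose(d.probs, 1 / 16)


def test_density_of_tone_peaks_at_tone_bin():
    dt = 1e-3
    sp = stft(_tone(200.0, 2048, dt), window_len=128, sample_interval=dt)
    d = freq_density(sp)
    assert d.probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert abs(sp.freqs[np.argmax(d.probs)] - 200.0) <= 7.8125
    assert d.probs.max() > 0.3


def test_density_zero_frames_skipped_with_warning():
    vals = np.ones((4, 8), dtype=complex)
    vals[2] = 0.0
    sp = Spectrogram(vals, np.arange(4.0), np.arange(8.0), "hamming", 8, 2)
    with pytest.warns(UserWarning):
        d = freq_density(sp)
    assert d.probs.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        freq_density(Spectrogram(np.zeros((2, 4), dtype=complex), np.arange(2.0), np.arange(4.0), "h", 4, 1))


def test_disjoint_bands_are_farther_apart_than_shared_bands():
    f = 32

    def band(lo, hi):
        p = np.zeros(f)
        p[lo:hi] = 1.0
        return p / p.sum()

    a1, a2 = band(2, 8), band(3, 9)
    b = band(20, 26)
    da = np.linalg.norm(a1 - a2)
    dab = np.linalg.norm(a1 - b)
    assert dab > da


def _brute_force(densities, amplitudes):
    """Independent re-enumeration oracle for the 3-center search."""
    m = len(densities)
    p = np.stack([d.probs for d in densities])
    best = (np.inf, None)
    for trip in combinations(range(m), 3):
        cost = 0.0
        for i in range(m):
            if i in trip:
                continue
            cost += min(np.linalg.norm(p[i] - p[j]) for j in trip)
        if cost < best[0] - 1e-15:
            best = (cost, trip)
    return best


@pytest.mark.parametrize("m", [4, 6, 10])
def test_search_matches_brute_force_oracle(m):
    rng = np.random.default_rng(m)
    densities = []
    for j in range(m):
        p = rng.random(24)
        densities.append(FreqDensity(p / p.sum(), j))
    amps = rng.random(m)
    res = search_centers(densities, amps)
    cost, trip = _brute_force(densities, amps)
    # ties (swapping a center with its closest member) are cost-degenerate,
    # so the oracle comparison is on the optimal cost
    assert res.total_distance == pytest.approx(cost, abs=1e-9)
    assert set(res.center_ids) == set(trip) or res.total_distance <= cost + 1e-9


def test_duplicate_components_force_zero_distance():
    """Three identical densities plus an outlier: the optimal triple keeps
    the outlier as a center and pays nothing."""
    base = np.array([0.5, 0.3, 0.2])
    other = np.array([0.1, 0.1, 0.8])
    ds = [FreqDensity(base, 0), FreqDensity(base, 1), FreqDensity(base, 2), FreqDensity(other, 3)]
    res = search_centers(ds, np.array([4.0, 3.0, 2.0, 1.0]))
    assert res.total_distance == pytest.approx(0.0, abs=1e-15)
    assert 3 in res.center_ids  # outlier must be a center for zero cost


def test_permuting_components_preserves_total_distance():
    rng = np.random.default_rng(5)
    ds = []
    for j in range(8):
        p = rng.random(16)
        ds.append(FreqDensity(p / p.sum(), j))
    amps = rng.random(8)
    res = search_centers(ds, amps)
    perm = rng.permutation(8)
    ds_p = [FreqDensity(ds[i].probs, k) for k, i in enumerate(perm)]
    res_p = search_centers(ds_p, amps[perm])
    assert res_p.total_distance == pytest.approx(res.total_distance, rel=1e-12)
    assert sorted(perm[list(res_p.center_ids)]) == sorted(res.center_ids)


def test_roles_follow_amplitude_ordering():
    rng = np.random.default_rng(9)
    ds = [FreqDensity((p := rng.random(12)) / p.sum(), j) for j in range(6)]
    amps = np.array([5.0, 1.0, 3.0, 0.5, 2.0, 4.0])
    res = search_centers(ds, amps)
    a, b, c = res.center_ids
    vals = {i: amps[i] for i in res.center_ids}
    assert res.roles["torso"] == max(vals, key=vals.get)
    assert res.roles["feet"] == min(vals, key=vals.get)


def test_insignificant_center_cannot_take_the_feet_role():
    rng = np.random.default_rng(11)
    ds = [FreqDensity((p := rng.random(12)) / p.sum(), j) for j in range(6)]
    amps = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 1e-5])
    res = search_centers(ds, amps, n_significant=5)
    assert res.roles["feet"] != 5 or 5 not in res.center_ids


def test_search_input_validation():
    ds = [FreqDensity(np.ones(4) / 4, j) for j in range(3)]
    with pytest.raises(ValueError):
        search_centers(ds, np.ones(3))
    ds40 = [FreqDensity(np.ones(4) / 4, j) for j in range(40)]
    with pytest.raises(ValueError):
        search_centers(ds40, np.ones(40))


def test_default_simulation_selects_low_band_torso_high_band_feet(default_fit):
    """On the walking echo the torso-role density concentrates at lower
    |frequency| than the feet-role density (quantile check)."""
    res = default_fit
    freqs = res.spectrogram(0).freqs

    def q75(d):
        order = np.argsort(np.abs(freqs))
        c = np.cumsum(d.probs[order])
        return np.abs(freqs[order])[np.searchsorted(c, 0.75)]

    dt = res.densities[res.search.torso_id]
    df = res.densities[res.search.feet_id]
    assert q75(dt) < q75(df)
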