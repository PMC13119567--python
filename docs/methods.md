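# Methods

## The simulator

The generator is a Boulic-style parameterized walking model: a deterministic
kinematic description of steady gait driven by two inputs, standing height H
and mean walking speed v.

**Gait timing.** The relative velocity is v_r = v/(k·H) and the walking
cycle T_c = 1.346/√v_r. The normalization constant k = 0.2602115 is the
model's single calibrated scalar, fixed once so that a 1.70 m subject at
0.7 m/s has T_c = 1.07 s; it is not touched thereafter. The cycle length is
L_c = v·T_c (the "stride" reported as ground truth) and the support (stance)
duration D_s = 0.752·T_c − 0.143 s, clamped to a 50–85% duty cycle. Whether
"cycle" names the full two-step period or one step is a semantic the
literature leaves loose; this package consistently treats T_c as the period
of each limb's motion (the torso oscillates at 2/T_c), and exposes
`cycle_convention` in the feature layer for the alternative readings.

**Pelvis trajectories.** Vertical and fore–aft sinusoids at twice the gait
frequency and a lateral sinusoid at the gait frequency, with the standard
relative amplitudes (e.g. fore–aft amplitude 0.021 for v_r > 0.5) scaled by
the thigh height 0.53·H. The fore–aft term is what makes the torso's radial
speed oscillate between ~0.48 and ~0.92 m/s at the default condition.

**Legs.** Ankle trajectories are prescribed: fixed on the ground during
stance (the hip passes over the ankle at mid-stance), advancing by L_c during
swing with a cycloidal (1 − cos) velocity profile whose peak is twice the
mean swing speed — this, projected on the line of sight, is what produces the
~3.5 m/s peak foot speed at 0.7 m/s walking. Ankle height follows the larger
of a straight-leg reachability bound (which creates heel-off and heel-rocker
naturally) and an asymmetric swing arc peaking in early-mid swing (heel
lift); a smooth soft-maximum joins the two so no velocity spikes are
injected. Knees come from two-link inverse kinematics, bending forward.

**Arms.** Swing in phase with the contralateral leg, amplitude
min(0.6, 0.35·v_r) rad with elbow flexion modulated in phase. The amplitude
matters more than it looks: with a large swing the arms dwell at their
reversal points *outside* the torso's Doppler band and merely flash through
the mid band; with a small swing they park inside the torso band and corrupt
its trajectory.

**Scatterers and RCS.** Each of the 16 segments is an ellipsoid with the
broadside reference cross-sections of the standard table (head 0.1257 m²,
torso 0.3068 m², foot 0.0177 m², ...), semi-axes scaling linearly with
height. Two defaults matter:

* `rcs_mode='oriented'`: σᵢ(t) is evaluated with the segment's instantaneous
  long-axis direction (limbs follow the bones, axial segments stay vertical,
  the foot's heel–toe axis pitches as the ankle lifts). A thin limb tilted
  15–30° off broadside returns 10–50× less power — without this, slow-moving
  near-vertical arms with torso-class cross sections make a clean torso
  trajectory impossible.
* `amplitude_mode='sqrt_rcs'`: segments enter the echo sum with field
  amplitude √σᵢ, since RCS is a power quantity. Weighting by σᵢ directly
  (available as `'rcs'`) doubles the torso-to-feet dynamic range in dB and
  pushes the feet subspace down to the numerical-leakage floor of the
  whitening stage.

**Noise.** The default simulation is noise-free. The feet return sits some
50 dB below the torso in echo power; receiver noise at even 40 dB SNR buries
the subspace the feet tracker relies on. `snr_db` adds seeded complex white
noise for robustness studies.

**What the generator does not emulate.** Range migration and range-gate
effects (one Doppler channel is synthesized directly), multipath and ground
bounce, body self-occlusion, clothing-dependent reflectivity, within-subject
gait variability beyond the per-sample parameter jitter used in the
classification protocol, and any non-steady gait (turns, starts, stops).
Passing tests therefore demonstrate correctness of the *method* under clean,
steady-gait conditions, not performance on measured radar data.

## Pipeline choices

**Whitening form.** The covariance is the M×M channel covariance
X̄X̄ᴴ/(K−1) of the delay embedding (complex, Hermitian). The pipeline uses
the eigenbasis ("PCA") whitening W = Λ^(−1/2)Uᴴ with components ordered by
descending eigenvalue: each component is then an eigen-filtered,
frequency-band-like view of the echo, which is what makes torso/feet
separation possible. The Hermitian zero-phase variant W = UΛ^(−1/2)Uᴴ is
retained (`whitening='zca'`) but its components stay near-copies of the
delayed channels and do not separate. Eigenvalue floor: 1e−10 of the largest
eigenvalue.

**Component amplitudes.** Whitened rows are unit variance by construction,
so their raw mean magnitude carries no scale. A component's amplitude is
defined as its back-projected contribution to the embedding channels,
rms(W⁻¹[:,j])·mean|z_j(t)|, which restores physical echo units, makes the
torso/feet role ordering an energy ordering, and gives taller subjects larger
torso amplitudes.

**Significance guard.** Components whose back-projected amplitude falls
below 1e−3 of the maximum (−60 dB in power) are whitened renditions of
empty Doppler bands — pure spectral leakage blown up to unit variance. They
carry no body-part information, yet their densities form a spurious chain
that captures search centers (and, being weakest, the feet label). The
3-center search therefore runs over the significant set only; the search
routine itself stays fully general.

**Densities and search.** Hamming window 128 samples, hop 32, FFT 128,
two-sided frequency axis (Doppler sign matters). Per-frame normalized
magnitudes are averaged over frames and renormalized into one probability
vector per component. The search enumerates all C(M,3) unordered center
triples exhaustively (1140 at M = 20; a guard caps M at 32) and is compared
against an independent brute-force enumeration in the tests. Cost ties occur
structurally — swapping a center with its own nearest member leaves the cost
unchanged — and are broken toward the lexicographically smallest triple.

**Tracker.** Window n = 200 samples, Hankel columns l = ⌊n/2⌋, order 1,
window step 1 (track length = input length − n + 1), timestamps at window
centers. The balanced square-root split Ω = U₁Σ₁^{1/2} is used for the
observability factor; pole estimates are invariant to the split (tested).
Poles map to decay α = −ln|λ|/Δt and frequency +arg(λ)/(2πΔt); the sign is
fixed so an approaching scatterer (echo phase −4πf r/c, r decreasing) gives
positive velocity. The rank-1 fast path runs a batched two-vector subspace
iteration (3 rounds, matched-filter start, fixed pseudo-random companion)
with an exact projected SVD, verified in the tests against per-window full
SVD; single precision inside the iteration is ample for pole phases.

**Knee point.** For the traditional baseline, the model order is the
maximum-perpendicular-distance point between the normalized singular-value
curve and its end-to-end chord, with a gap-ratio rule deciding whether the
knee sample itself is signal or noise. On the raw default echo this yields
order 10. (A log-scale knee chases the numerical tail of a noise-free
spectrum and lands near 20.)

**Baseline.** The order-k tracker emits k poles per window, associated into
continuous tracks by greedy nearest-frequency matching (ties toward the
lowest index). Curve selection against a reference — the reproducible
stand-in for picking curves by eye — ranks tracks by mean absolute velocity
difference. Baseline torso amplitude comes from per-window Vandermonde
least-squares amplitudes of the torso-associated mode.

**Features.** Peak clusters: local maxima at least a quarter track apart,
the tallest adjacent pair kept, each averaged over the contiguous run within
`speed_band` (0.2 m/s) of the peak. Cycle = 2× the cluster interval (both
the torso oscillation and the two-feet envelope peak twice per gait cycle;
`'interval'` and `'half'` conventions are exposed). The cycle feature is
taken from the feet curve, whose sharp swing peaks localize far better than
the broad torso oscillation (measured: ~0.1–0.9% versus ~5% error). Stride:
trapezoidal integral of speed over one cycle centered on the peak clusters,
shifted inside the track if it would overrun either end; halved for the feet
curve. The amplitude feature is excluded from classification vectors by
default (clothing-dependent in reality).

**Classifier.** One RBF-SVM (C = 1, gamma='scale') per class pair, feature
standardization fitted on each pair's training fold, 30 training samples per
class drawn by seed, one vote per pairwise decision, ties toward the lowest
label. The SVM itself is scikit-learn's; the voting protocol, splits and
tie-breaks are this package's.

## Known limitations

* **Feet stride at slow speeds.** Between swings (double support) the arms
  sweep 0.7→1.6 m/s through the lower part of the feet component's band;
  the rank-1 pole faithfully reads that genuine limb echo (|λ| ≈ 1), so the
  one-cycle integral of the feet curve overshoots by ~10–20% at 0.5–0.7 m/s
  walking. At 1.0–1.2 m/s (shorter double support) the same pipeline reaches
  0.7–4% feet-stride error. The torso-curve stride is the more reliable
  stride estimate throughout, which is also why it is the one used in the
  classification feature vector.
* **Torso amplitude.** Separation is never perfect: the torso component
  also absorbs the co-moving head, shoulder and hip returns, so its
  back-projected amplitude overestimates the torso-only echo strength by
  ~30–50%. The feature is monotone in subject size but not calibrated.
* **Synthetic walker separability.** Under the per-sample 3% Gaussian
  jitter of the classification protocol, the four nominal walkers (who
  differ by as little as 4% in speed) overlap irreducibly: even classifying
  exact kinematic features yields ~73% mean accuracy, and the full pipeline
  reaches ~69%. Real walkers differ in gait style, not just in a
  (height, speed) rescaling, so measured-data accuracies are not comparable.
* The exhaustive search is O(M³) and intentionally capped at M = 32.
* All error figures quoted here are produced by the test suite and
  `scripts/acceptance.py` on the synthetic conditions described above.
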