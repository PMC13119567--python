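# microgait

Micro-Doppler gait analysis for radar: simulate walking-human echoes with the
Boulic kinematic model, separate torso and feet returns by whitening plus a
frequency-probability-density search, extract their time–velocity
trajectories with a rank-1 sliding-window state-space method, derive physical
gait features, and classify walkers with a one-vs-one SVM voting scheme.

## Who this is for

Radar and biomedical signal-processing researchers who want interpretable,
*physical* gait features (walking cycle, stride length, peak torso and foot
speeds) from a single slow-time Doppler channel — as opposed to opaque
deep-learning features on spectrogram images — and a reproducible synthetic
test bed to develop them on.

## The method

A walking body is modelled as 16 ellipsoid scatterers (head, shoulders, arms,
torso, hips, legs, feet) whose radar cross-sections follow

σ = π a²b²c² / (a² sin²θ cos²φ + b² sin²θ sin²φ + c² cos²θ)²,

and whose positions follow a calibrated Boulic walking model (cycle
T_c = 1.346/√v_r with v_r the height-normalized relative velocity). The
complex slow-time echo is s(t_k) = Σᵢ σᵢ exp(−j4πf rᵢ(t_k)/c).

The extraction pipeline:

1. **Embedding** — the 1×N echo becomes an M×K matrix of delayed channels
   (M = 20).
2. **Whitening** — the channel covariance Σ = X̄X̄ᴴ/(K−1) is eigendecomposed
   and W = Λ^(−1/2)Uᴴ yields M unit-variance components, each an
   eigen-filtered view of the echo.
3. **Component search** — every component gets a frequency probability
   density (per-frame-normalized spectrogram magnitude, time-averaged); an
   exhaustive C(M,3) search picks the three centers minimizing the total
   nearest-center distance, and amplitude ordering labels them torso / other
   / feet.
4. **Rank-1 state-space tracking** — inside each length-200 sliding window a
   Hankel matrix H[r,c] = x[r+c] is formed; with the model order fixed at 1,
   the dominant singular vector's shift invariance gives the signal pole λ,
   hence the instantaneous frequency arg(λ)/(2πΔt) and radial velocity
   (approach-positive).
5. **Features** — peak speeds, walking cycle (twice the interval between the
   two dominant peak clusters), stride length (one-cycle integral of the
   velocity curve, halved for the two-feet curve), torso amplitude.
6. **Classification** — one RBF-SVM per walker pair, one vote per pairwise
   decision, argmax of votes.

## Worked example

```python
from microgait import WalkParams, GaitMicroDoppler

params = WalkParams(height=1.70, velocity=0.7)   # 15 GHz, 2 kHz PRF defaults
model = GaitMicroDoppler.from_simulation(params)
result = model.fit()
print(result.summary())
```

prints (abridged):

```
Gait micro-Doppler feature extraction
=======================================================
echo: N=2675  dt=5.00e-04 s  fc=15 GHz
components: M=20  centers=(0, 1, 6)  roles: torso=0 feet=6  D=0.4045
-------------------------------------------------------
feature                   estimate       truth    err %
-------------------------------------------------------
Torso amplitude           0.7382       0.5539    33.27
Walking cycle              1.069 s       1.07     0.14
Max torso speed           0.9422 m/s     0.915     2.98
Max feet speed             3.484 m/s     3.526     1.17
Stride (torso curve)      0.6508 m      0.749    13.11
Stride (feet curve)       0.8775 m      0.749    17.16
```

Reading this: components 0 and 6 of the whitened set were selected as the
torso and feet echoes; the tracked torso curve peaks at 0.94 m/s versus the
kinematic truth 0.92 m/s (3%), the feet envelope at 3.48 versus 3.53 m/s
(1.2%), and the walking cycle lands within 0.2%. Stride estimates integrate
the tracked curves and inherit whatever the curves read between swings (see
`docs/methods.md` for why the feet stride is the weakest feature at slow
walking speeds).

`result.plot_tracks()` overlays both trajectories on the echo spectrogram.
A thin CLI wraps the same functionality:

```
microgait simulate --height 1.70 --velocity 0.7 --out echo.csv
microgait extract --echo echo.csv
microgait classify --samples 100
```

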