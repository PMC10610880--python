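# Methods

This note documents the models implemented in `epiopt`, the defaults and
why they were chosen, what the synthetic phantom does and does not
emulate, and the numerical choices that affect results.

## Sequence timing model

A single-shot 2-D GRE-EPI readout is described by its echo train length
(ETL, one phase-encode line per gradient echo), echo spacing (esp), and a
preparation interval between excitation and the start of the readout.
With linear phase-encode ordering the k-space center is crossed ETL/2
echoes into the train, giving

```
min_TE  = prep_time + esp·ETL/2
dead    = TE − prep_time − esp·ETL/2      (must be ≥ 0)
TAD     = ETL · esp
PE bandwidth = 1 / TAD    (per pixel)
```

Geometric distortion from off-resonance scales inversely with the PE
pixel bandwidth, so the ratio of two bandwidths is reported directly as a
distortion-improvement factor.

**Echo spacing derivation.** When not given, esp is the flat-top readout
time (`n_readout / total bandwidth`) times `1 + ramp_fraction`.  The
default `ramp_fraction = 0.034` is calibrated so that a 60-sample readout
at 160 kHz yields ≈ 43 Hz/pixel PE bandwidth, the value characteristic of
the high-performance head-gradient systems this package targets; on such
hardware ramps are a small fraction of the echo spacing.  It is
configurable per protocol for slower gradient sets.

**TR model.** Multi-slice coverage forces `TR = n_slices · (TE + c)`.
The per-slice overhead `c` is calibrated from a (TE, TR) table by
least squares with the slope fixed at `n_slices` (both built-in reference
tables are exactly linear with that slope; residuals ≤ 0.9 ms).  For the
built-in families `c` = 20.76 ms (3.4 mm, 38 slices) and 18.31 ms
(4.0 mm, 32 slices).  `prep_time` defaults to 3 ms; it shifts absolute
dead times only and cancels out of every optimization result.

## Contrast efficiency

`SNR_BOLD ∝ V · TE · √TAD · f(α,TR,T₁) · exp(−TE/T₂*)` with the spoiled
steady-state term `f = (1−E)sin α/(1−E cos α)`, `E = e^(−TR/T₁)`.  The
TE factor is linear (BOLD sensitivity of the magnitude signal to a T₂\*
perturbation) while the readout duration enters as √TAD (noise averaging
over the acquisition window).  TAD is constant within each protocol
family, so the location of the efficiency optimum is insensitive to the
TAD exponent; the TE·√TAD form is the one that reproduces the 55 ms
optimum on the 3.4 mm reference grid.  The proportionality constant is
K = 1: all SNR/η values are arbitrary units and only ratios matter.

Grid-mode optimization evaluates η at the supplied (TE, TR, FA) rows —
with the integer flip angles of the table when given, which differ from
the exact Ernst angles by < 0.1% in signal — and breaks exact ties toward
the smaller TE.  Continuous mode maximizes η(TE) with a user-supplied
TR(TE) and the exact Ernst angle, by bounded scalar minimization
(xatol 1e-8 ms).  With TR decoupled from TE this recovers the textbook
optimum TE = T₂\* to < 0.01 ms; with TR strictly increasing in TE the
optimum always falls below T₂\*.

**Known near-tie.** On the 4.0 mm reference grid η(65 ms) exceeds
η(55 ms) by 5×10⁻⁴ relative — far below anything measurable — so the
reported grid optimum for that family is 65 ms.  Which side of the tie an
evaluation lands on depends on whether integer or exact flip angles are
used and on the T₂\* input; only the 3.4 mm optimum (55 ms) is robust.

## Relaxometry

Default fitter: weighted log-linear regression of `ln S` on TE with
weights ∝ S², which equals signal-domain least squares to first order in
the noise and is exact (machine precision) on noiseless data.  Optional
`nonlin` refinement runs Levenberg–Marquardt in signal space from the
log-linear start.  Echoes below 3× a supplied background-noise estimate
are excluded; no Rician bias correction is applied because the intended
regime is magnitude SNR ≥ 10.  Fits are flagged invalid — never silently
zeroed — when fewer than 3 echoes survive, the signal does not decay
(fitted decay rate ≤ 1e-9 /ms), r² < 0.8, or T₂\* falls outside
[1, 2000] ms.  r² is computed in signal space over the included echoes.
At echo SNR 50 and the 26-echo grid the estimator's T₂\* bias is < 2%;
it vanishes as SNR grows (checked at SNR 20/50/200).

## SNR engine

Reconstruction is a centered orthonormal 2-D inverse FFT per slice and
coil followed by root-sum-of-squares (RSS) combination; orthonormal FFTs
make white k-space noise map to white image noise and keep Parseval
equality exact.  Ψ is the covariance of circular complex coil noise,
`E[n nᴴ] = Ψ` (real/imaginary parts each Ψ/2); replicas are colored by
the Cholesky factor of Ψ.  pSNR is voxel-wise mean/SD over replicas —
deliberately the same functional as tSNR (mean/SD over repetitions) so
that the decomposition `σP/σT = √((pSNR/tSNR)² − 1)` is internally
consistent.  Where sampling noise makes pSNR < tSNR the ratio is NaN,
never imaginary.  Defaults: 128 replicas, 64 repeats.  Statistics are
treated as Gaussian on magnitude data; below SNR ≈ 10 the RSS magnitude
becomes noncentral-chi distributed and pSNR acquires a known upward bias
relative to tSNR — low-SNR operation is out of scope.

ROI summaries report **both** decomposition variants: the ratio computed
from ROI-mean pSNR and tSNR (`ratio_of_means`, the stable estimator used
for recovery checks) and the ROI mean of voxel-wise ratios
(`voxel_ratio_mean`, with the fraction of defined voxels), since the two
differ under spatial heterogeneity.

## Digital phantom

Geometry: a WM ellipsoid core inside a GM ellipsoidal shell, with the
posterior 30% of the shell labeled "visual cortex" — concentric
ellipsoids rather than atlas anatomy, because only the ROI semantics
(GM/WM/VC with distinct T₂\*) matter to any result here.  Defaults:
grid 48×48×12 at 4 mm isotropic, 16 coils (Gaussian-lobe sensitivities
with phase ramps; Ψ = identity + 0.1 off-diagonal coupling), T₁ 717.2 ms
everywhere, T₂\* 86.3/77.9/78.5 ms in GM/WM/VC, proton densities
0.8/0.7/0.8.  The voxel signal carries an explicit voxel-volume factor,
so at fixed k-space noise larger voxels have proportionally higher
baseline SNR — the lever behind the voxel-size dependence of σP/σT.
Thermal noise is set either by a target GM-mean pSNR (default 50,
representative of mid-field fMRI voxels) or by an explicit k-space sigma.

Physiological signal model (two-term, Krüger–Glover-like):

```
S_t = S · (1 + λ_const·g_t + λ_bold · TE·e^(−TE/T₂*) · h_t)
```

with `g, h` unit-variance AR(1) processes.  The TE-weighted term makes
the injected σP/σT grow as TE → T₂\*; the constant term models
signal-proportional non-BOLD fluctuation.  Analytic per-voxel ground
truth is returned with every simulation: σP = S·√(λ_c² + (λ_b·w)²),
σT from the linearized RSS noise propagation `√(sᴴΨs/2)/‖s‖`.
λ values for a desired ROI-level ratio are solved by root-finding on the
analytic summary, so "injected ratio 0.5" is exact by construction, and
recovery is a like-for-like comparison of the same summary functional on
estimated vs analytic maps.

Two deliberate departures from physiological realism, both documented
because they change what passing tests prove:

* **AR(1) coefficient 0.7** (not higher): with 64 frames, the sample
  variance of an AR(1) process with coefficient ρ is biased low because
  mean removal absorbs low-frequency power — ≈ 24% at ρ = 0.9 but ≈ 7% at
  ρ = 0.7, keeping σP estimable from a 64-frame series.  Real respiratory
  / cardiac-aliased fluctuations can be more strongly autocorrelated.
* **No spatial correlation** of g, h between voxels: ROI averaging then
  genuinely reduces temporal-variance estimation noise.  Real physiological
  noise is spatially structured, so in-vivo ROI estimates at 64 frames
  would be noisier than the phantom suggests.

EPI sampling is ideal Cartesian — no trajectory, ghosting, or T₂\* decay
across the readout — so the forward model is exactly inverted by FFT+RSS
and every SNR deviation is attributable to the injected noise.
Consequently the phantom validates the estimators and the noise
decomposition, not EPI artifact behavior.

## Problem sizes and determinism

Simulation-based tests and the validation pipeline run at 32×32×8 (or
smaller) grids with the full 64-repeat / 128-replica defaults; these grid
sizes give ~1500 GM voxels, enough for ROI statistics with sub-percent
sampling error, and were chosen as the package's standard small-problem
configuration.  All stochastic stages take explicit seeds; identical
spec + seed reproduces outputs bit-for-bit, and pipeline manifests record
every stage seed.  At these sizes the σP/σT ROI recovery at injected 0.5
lands within ~5% of truth (dominated by the AR(1) variance bias discussed
above, amplified ~5× by the derivative of the decomposition at ratio 0.5).

## Known limitations

* No parallel imaging (g-factor), motion, B₀ maps, slice profiles, or
  multi-echo EPI readouts; magnitude-Gaussian noise regime only.
* The TR = n_slices·(TE + c) model is exactly linear; real sequences may
  quantize TR.  A reported "TR saved" of ≈ 1178 ms for the 3.4 mm family
  (38 slices × 31 ms) follows from this model.
* The efficiency metric compares protocols within a family (fixed
  resolution and readout); cross-resolution comparisons carry the voxel
  volume and TAD factors but no partial-volume or smoothing effects.
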