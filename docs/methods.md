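# Methods

## The phantom

The simulator emulates a single-slice DSC-MRI bolus-tracking acquisition as a
labelled population of voxel time–signal curves on a uniform grid (default
1 s sampling over 90 s, with sample 0 at t = 0 and the arrival time t₀ = 26 s
falling on a sample, so the sampled peak of the arterial model is
reproducible to the printed precision).

**Arterial model.** The main first-pass peak is the gamma variate
`g(t) = A (t−t₀)^α e^{−(t−t₀)/β}` (A = 1, α = 3.0, β = 1.5 s), zero at and
before arrival. Recirculation is `K·[g(t−t_d) ⊗ e^{−t/τ}]` with delay
t_d = 8 s and dispersion τ = 30 s, computed by rectangle-rule discrete
convolution on the sampling grid. K is fixed *per grid* so that the sampled
recirculation peak is exactly one third of the sampled main peak; a stored
constant would silently go stale when the grid changes. On the default grid
the sampled maximum is 4.4592 (at t₀+5 s; the continuous maximum 4.5368 sits
at t₀+αβ = 30.5 s, between samples).

**Tissue model.** Each tissue voxel draws an MTT from a normal distribution
(class mean ± sd, truncated below at 0.1 s to keep CBF finite) and forms
`C_t = (ρ/k_H)·CBF·(C_a ⊗ r)` with CBF = (CBV/100)/MTT in ml g⁻¹ s⁻¹. The
residue kernel is the dispersed-exponential gamma variate
`r(t) ∝ t·e^{−2t/MTT}`, the simplest one-scale gamma-variate family that
vanishes at the origin, rescaled so its rectangle-rule integral equals MTT —
which makes CBF·∫r = CBV hold by construction (central volume theorem). All
convolutions use the rectangle rule (× dt) consistently.

**Signal model and calibration.** `S = S₀ e^{−k·TE·C}` with S₀ = 100 and
TE = 0.03 s. k is calibrated once, from the mean-MTT normal-GM concentration
curve, in closed form `k = −ln(0.6)/(TE·max C_GM)`, so that curve's signal
dips exactly 40% below baseline; the same k is reused for every voxel. With
the default parameters k·TE ≈ 2.8, so the arterial signal at peak drops to
~0.04% of baseline — deep but strictly positive, and exactly invertible.

**Population.** 6 identical true-arterial voxels; 16 false-arterial voxels
from the 4×4 grid of arrival delays (+1…+4 s) × recirculation delays
(+1…+4 s); 440 + 440 + 600 tissue voxels; 400 partial-volume voxels formed as
convex combinations `w·S_arterial + (1−w)·S_tissue` **in signal space**
(weight w ~ U(0,1), tissue partner uniform over the three classes). Signal-
space mixing is the natural reading of "mixing of signals" and has a
consequence worth knowing: because concentration is the negative log of
signal, the arterial component saturates, so a partial-volume voxel's
concentration curve looks like a clipped plateau of height ≈ −ln(1−w)/(k·TE)
rather than a scaled arterial peak. There is no additive noise model: the
only variability is the population variability stated above.

## Detection pipeline

Signals are inverted to concentration per curve (`C = −ln(S/S₀)/(k·TE)`;
signals ≤ 10⁻⁶·S₀ are clipped to that floor so the map stays total; when k is
unknown, as in clinical data, k = 1 is used — every downstream statistic is
scale-invariant or comparative). Clustering operates on the raw concentration
time series (no area normalization by default; a `normalize_area` option
exists), with k = 5 clusters, centroids initialized as 5 distinct curves
drawn uniformly at random (seeded), one run per detection call. K-means is
Lloyd iteration with squared-Euclidean distance, convergence on stable
assignments, and empty clusters repaired by reseeding onto the farthest
point. FCM uses the standard alternating membership/centroid updates with
fuzziness m = 2.0 (the conventional value), stopping when the largest
membership change falls below 10⁻⁵; hard labels are the row-wise argmax, ties
to the lowest index. For both methods the candidate AIF of a cluster is the
plain mean of its member curves, scored with M = PV/(TTP·FWHM); the highest
eligible M wins.

Numerical conventions for the shape statistics: PV is the maximum sample;
TTP is the time of the *first* maximal sample, with no sub-sample
interpolation; FWHM interpolates linearly at half maximum, taking the first
crossing left of the peak and the last crossing right of it, and is declared
undefined (making the cluster ineligible) when the curve never drops below
half maximum on either side; AUC is the rectangle-rule integral. One known
tension follows from the TTP convention: the model's continuous peak sits at
t₀ + αβ = 30.5 s, so no sampling convention yields the sometimes-quoted
29.51 s for the true curve; this package reports its own sampled TTP (31 s on
the default grid) and never asserts that value.

## Pre-filters and where they apply

The clinical pipeline removes, in order, the 90% of pixels with the smallest
concentration AUC and then the 25% of survivors with the largest roughness
integral `∫C″(t)² dt` (discretized as summed squared second differences over
dt³). Exclusion counts use `floor(fraction·n)`; ties are broken by original
index with lower indices retained, making the filters deterministic and
idempotent. On the default 1902-voxel phantom the counting rule gives
1902 → 191 → 144.

The simulation comparison deliberately does **not** pre-filter. In a
noise-free phantom the roughness integral is maximized by exactly the
curves one wants to keep: roughness scales with squared amplitude, and even
after unit-area normalization the arterial bolus is the sharpest shape in the
population, so any roughness ranking removes all 22 arterial voxels before
any partial-volume voxel. Roughness filtering earns its keep only when
high-frequency noise — absent here by design — dominates the second
differences of weak pixels. The repeatability experiment, whose clinical
analogue runs after filtering, keeps the pre-filtering step.

## Experiments and their problem sizes

* **Simulation comparison** — one default phantom (1902 voxels × 90 samples),
  both methods on the same detection seed; reports PVE, PV, TTP, FWHM, AUC,
  RMSE (vs the true AIF, over all 90 samples) and M per method, plus the
  ground-truth row, with per-method wall-clock recorded but never asserted.
* **Directional comparison** — 20 phantom/detection seed pairs; the
  comparison surface is the *ordering* of mean RMSE (K-means below FCM), not
  any particular value: absolute RMSE depends on the unrecorded random
  partial-volume weights and initializations of any given run.
* **Repeatability** — one phantom, pre-filtered, 50 detections per method
  varying only the clustering seed; the robustness score is the mean
  per-timepoint variance of the 50 detected AIFs (exactly zero for
  bit-identical runs, by an explicit short-circuit that avoids floating-mean
  residue).
* **Clinical mode** — a 4D NIfTI volume, first two frames discarded, slice
  extracted, per-pixel baseline from the first 5 retained frames (the bolus
  arrives at the seventh acquired frame, so five pre-bolus frames remain
  after the discard), then the filtered pipeline above.

## What the phantom does and does not show

The phantom reproduces the anchor quantities of the arterial model (sampled
peak 4.4592, interpolated FWHM ≈ 6.20 s, calibrated 40% GM signal drop) and
the qualitative structure of the detection problem (a small, separable
arterial population contaminated by delayed and partial-volume curves). It
contains no thermal noise, no motion, no T1 leakage and no spatial structure.
Two consequences matter for interpreting results. First, both clustering
methods find the arterial cluster easily, so accuracy differences are small
and the RMSE ordering is a weaker signal than in noisy data. Second,
run-to-run instability of FCM — reported on clinical data, where noise and
overlapping clusters create competing optima — largely does not manifest:
on unfiltered phantom curves both methods are bit-stable across seeds, and on
pre-filtered curves (a near-continuum of partial-volume plateaus with no
arterial members) K-means, not FCM, is the seed-sensitive method, because the
hard objective has many near-tied local minima while the fuzzy objective has
a single strong attractor. The repeatability assertion in the acceptance
suite therefore fails under these study conditions and is left failing
rather than re-tuned; a noise model would be required to probe it, and noise
is deliberately out of scope for this phantom.

## Defaults worth knowing

| Parameter | Default | Why |
|---|---|---|
| dt, duration | 1 s, 90 s | 90-sample scan; arrival on-grid |
| α, β, t₀, t_d, τ | 3.0, 1.5 s, 26 s, 8 s, 30 s | stated bolus model |
| recirculation ratio | 1/3 | stated peak ratio, fixed per grid |
| S₀, TE | 100, 0.03 s | stated signal model |
| ρ, k_H | 1.04 g/ml, 0.73 | density, hematocrit correction |
| GM calibration drop | 40% | stated calibration condition |
| p_auc_low, p_rough | 0.90, 0.25 | stated clinical filter fractions |
| clusters, FCM m, tol, max_iter | 5, 2.0, 1e-5, 300 | stated cluster count; conventional FCM settings |
| MTT truncation | 0.1 s | keeps CBF = CBV/MTT finite |
| baseline window n_pre | 5 frames | injection timeline after frame discard |
| clinical dt fallback | 1.5 s | typical repetition time |
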