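# dscaif

Automatic arterial-input-function (AIF) detection for dynamic susceptibility
contrast (DSC) perfusion MRI, with a simulation phantom to compare the two
standard clustering backends — K-means and fuzzy c-means (FCM).

Quantitative DSC perfusion (CBF, CBV, MTT maps) requires the AIF: the
contrast-agent concentration over time in a brain-feeding artery, used as the
divisor in the deconvolution of tissue time–concentration curves. Manual AIF
selection is slow and operator-dependent; automatic methods cluster the
voxelwise concentration curves and pick the most arterial-looking cluster.
This package implements both clustering backends end-to-end, a fully synthetic
phantom to evaluate them against a known ground truth, and a clinical mode for
pre-aligned 4D NIfTI volumes.

## The model

**Arterial input.** The bolus first pass is a gamma variate with a delayed,
dispersed recirculation peak:

```
C_a(t) = g(t) + K · [g(t − t_d) ⊗ exp(−t/τ)],   g(t) = (t − t_0)^α e^{−(t−t_0)/β}  for t > t_0
```

with α = 3.0, β = 1.5 s, t₀ = 26 s, t_d = 8 s, τ = 30 s, and K fixed so the
recirculation peak is one third of the main peak.

**Tissue curves.** Indicator dilution: `C_t(t) = (ρ/k_H) · CBF · (C_a ⊗ r)(t)`,
where r is a dispersed-exponential residue kernel with integral MTT, CBF =
CBV/MTT (central volume theorem), ρ = 1.04 g/ml, k_H = 0.73. Classes: normal
GM (CBV 4 ml/100 g, MTT 4 ± 0.33 s), pathological GM (3.3, 10 ± 0.7 s), normal
WM (2, 5.45 ± 0.33 s).

**Signal model.** `S(t) = S₀ exp(−k·TE·C(t))` with S₀ = 100, TE = 30 ms and k
calibrated so the normal-GM signal dips exactly 40% below baseline. The
default phantom holds 1902 voxels: 6 true arterial, 16 delayed "false"
arterial, 1480 tissue, and 400 partial-volume voxels mixing arterial and
tissue signal with uniform random weights.

**Detection.** Signals are inverted to concentration, clustered into 5 groups
(K-means or FCM), and each cluster's mean curve is scored with
`M = PV/(TTP·FWHM)` (peak value / time-to-peak / full width at half maximum);
the highest-M cluster is the AIF. Clinical mode first drops the two
pre-steady-state frames and removes weak and irregular pixels (the 90%
lowest-area curves, then the 25% roughest by the integral of the squared
second derivative). Evaluation uses the partial-volume fraction of the
selected cluster, the shape statistics, AUC, RMSE against the true AIF, and —
for repeated runs — the mean per-timepoint variance of the detected AIF.

## Worked example

```sh
dscaif compare --phantom-seed 7 --detect-seed 11 --out report.csv
```

prints

```
                 PVE     PV     TTP   FWHM     AUC   RMSE      M
AIF
FCM-based     0.7273 3.8826 33.0000 7.4629 75.2448 0.4643 0.0158
K-Means-based 0.7273 3.8826 33.0000 7.4629 75.2448 0.4643 0.0158
True          0.0000 4.4592 31.0000 6.3044 76.6890 0.0000 0.0228
```

Each row is one AIF estimate. For this phantom seed, both methods select the
same 22-voxel arterial cluster: its 6 true arterial members plus 16 delayed
false-arterial voxels give a partial-volume fraction (PVE) of 16/22 = 0.7273,
and averaging over the delayed members lowers and broadens the mean curve
relative to the truth (PV 3.88 vs 4.46, FWHM 7.46 vs 6.30 s), which is what
the RMSE of 0.46 measures. On other seeds the methods differ; across 20
replicates K-means attains a lower mean RMSE than FCM.

Other subcommands: `dscaif simulate` (write a phantom as TSV + YAML sidecar,
optionally NIfTI), `dscaif detect` (cluster a stored phantom), `dscaif repeat`
(repeatability study; reports the robustness variance), and `dscaif clinical`
(detection on a 4D NIfTI volume).

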