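# Methods

This note records the models, conventions and numerical choices behind
`dtpa`, and what the synthetic phantom does and does not establish.

## Signal model and difference images

All analysis operates on `D_k(x) = S_0(x) − S_k(x)` with `S_0` the baseline
image (`baseline_index`, default 0; configurable to skip non-steady-state
leading frames). Positive `D` means susceptibility-induced signal drop
(intravascular contrast, intact BBB); negative `D` means T1 enhancement
above baseline (leakage). The baseline frame of `D` is identically zero, so
its local variance is degenerate there — the standardized moments (skewness,
excess kurtosis) are *invalidated* on such frames rather than forced to
zero, and interval averages simply skip undetermined frames. On noisy real
data baseline variance is positive and the baseline skew/kurt are defined.

Tissue concentration uses the standard dynamic susceptibility contrast
relation `C(t) = −(1/TE)·ln(S(t)/S(0))`. It is used only for bolus-phase
detection, never for reported statistics, so its scale convention is
immaterial downstream.

## Twofold normalization

* **Coil load**: the whole raw series is divided by
  `mean(reference region at baseline) / c_ideal`. `c_ideal` defaults to 100;
  any positive constant gives identical test statistics because every tissue
  shares the factor.
* **Cardiac output**: the difference series is divided by `A / auc_ref`,
  where `A` is the trapezoidal area under the reference-region difference
  curve over IFP ∪ OFP, sampled at unit time-index spacing with endpoints
  inclusive, and `auc_ref = 200`. Division (rather than multiplication) is
  the only orientation for which the post-condition "the recomputed area
  equals `auc_ref`" holds, and both fixed points (baseline mean = `c_ideal`,
  area = `auc_ref`) then hold simultaneously and exactly.

The cardiac normalization is applied to the *difference* series and hence
propagates to every kernel map derived from it; ORIG keeps only the
coil-load normalization. Because the underlying signal model is
`S = B·exp(−TE·C)`, scaling the bolus amplitude is not an exact scaling of
`D`; after AUC normalization a systematic second-order residual remains.
With the default 25% peak drop it is ≈0.8% on the IFP/OFP interval means of
a ×1.5 amplitude pair and ≈3.6% on RPP (outside the calibrated window). The
paired-run agreement test therefore checks the calibrated intervals, and
the cardiac-pair fixture is generated noise-free: with noise, the two runs'
common noise realization is divided by different AUC factors, adding
seed-dependent jitter that obscures the property under test.

## Bolus-phase segmentation

Detection runs on the reference-region concentration curve smoothed with a
centered moving average (`smooth_width = 3`, reflected ends). Baseline mean
μ and standard deviation σ are taken over pre-peak samples below 10% of the
maximum; the time of arrival is the first index above `μ + k_sigma·σ`
(`k_sigma = 3`) sustained for two consecutive samples; the peak is the
global maximum; the post-peak minimum is the first interior local minimum.
These three constants are config-exposed; they are detection conventions,
not physiology. Interval boundaries are fixed as `BLP = [0, toa)`,
`IFP = [toa, peak]`, `OFP = (peak, min]`, `RPP = (min, end]`, which
guarantees the four intervals partition the time axis. When no interior
minimum exists (short acquisitions), the final sample is ceded to RPP and
OFP shortened by one, keeping every interval non-empty (logged as a
warning). Detection is invariant to positive scaling of the curve.

## Texture parameter maps

Kernels are 2D squares of odd side `w` (default 3, the smallest meaningful
window; 5 is exercised in tests) and never cross slice boundaries — 5 mm
slices make through-plane neighborhoods strongly anisotropic. Local moments
are population (divide-by-n) central moments; implementation uses a box
filter over raw power sums of the frame-mean-centered image, which agrees
with a per-voxel double loop to ≈1e−13 relative. The border band of width
`(w−1)/2` is flagged invalid; VAVA's band is twice as wide because it is the
local-variance filter applied a second time to the VARI map. The two-pass
VAVA is the default because, unlike the within-kernel closed form
`m4 − m2²`, it does not behave as an edge detector; the closed form remains
available (`vava_mode="closed_form"`). SKEW/KURT are invalidated where the
local variance is below `1e−12 × (frame dynamic range)²`. KURT is *excess*
kurtosis (Gaussian → 0).

At the TOI level the variance-of-variance statistic uses the closed form
`m4 − m2²` (the variance of the squared deviations): a flat set of region
values admits no second spatial pass.

Whether TOI statistics are computed per time point and then interval
averaged, or on time-averaged maps, is a genuine design fork; the
per-time-point order is used because interval comparability is the stated
purpose of the time averaging.

## Statistical battery

Each (TPM, statistic, interval) cell groups the per-TOI record values by
tissue class. A one-way fixed-effects ANOVA (p < `gate_alpha` = 0.05) gates
the three pairwise two-sided Wilcoxon rank-sum tests. The ANOVA is used as a
gate despite the non-normality of texture parameters — a deliberate
fidelity-over-optimality choice. The exact rank-sum p enumerates all
`C(n+m, n)` assignments of pooled mid-ranks (a permutation test, valid under
ties; feasible to `n+m ≤ 12`); the large-sample mode uses the normal
approximation with tie-corrected variance and continuity correction, and is
verified against scipy. BH adjustment defaults to the smallest defensible
family — the three pairwise tests of one cell, matching how results tables
present three adjusted columns per row — with per-TPM (72) and global (576)
scopes selectable. Undetermined records are excluded; cells that cannot be
tested are reported as skipped, never as zeros.

The counting report prints significant-test counts per TPM × interval with
totals, the number of analysis cells per TPM (72 = 6 × 4 × 3; the count is
the same whether the factor 3 counts tissue classes or tissue pairs), the
576 possible tests and the expected false-positive count `576 × α = 28.8`.
The null-calibration test operationalizes that yardstick as: the *mean*
significant-test count per battery, over 100 independent null phantoms with
the gate disabled and raw p-values, must lie in the binomial 99% interval
around 28.8. The per-battery count itself is over-dispersed relative to a
binomial because the 576 tests share TOIs and are correlated; the mean
across independent seeds is the quantity the expectation argument actually
pins down. The observed mean (≈27, slightly conservative) reflects the
discreteness of the rank-sum distribution at 12-per-group and the
continuity correction.

## Synthetic phantom

Per voxel of tissue τ:

```
S(t, x) = B(x) · exp(−TE · c_τ(t)) + l_τ · Cum_τ(t) + ε(t, x)
```

* `B(x)`: per-tissue baseline mean (default 400) plus an i.i.d. Gaussian
  texture field (default sd 15, ≈3.75%).
* `c_τ(t)`: gamma-variate first pass
  `A·((t−t0)/(αβ))^α·exp(α−(t−t0)/β)` (onset `t0 = 8` time indices,
  `α = 3`, `β = 1.5`, peak exactly `A` at `t0+αβ`) plus a recirculation bump
  (delay 9.5 indices, twice the scale, 22% amplitude) that creates the
  post-peak local minimum the phase detector needs. The default amplitude
  gives a 25% peak signal drop at TE 47 ms — a realistic white-matter
  first-pass effect at 1.5 T.
* `l_τ·Cum_τ(t)`: leakage as cumulative contrast uptake (trapezoidal
  integral of `c_τ`), an intentionally model-free stand-in for
  extravasation — only the sign and monotonicity of late enhancement are
  emulated, since avoiding pharmacokinetic modelling is the point of the
  method. The effect fixture's default `l = 600` produces ≈4% late
  enhancement over baseline, enough to flip the reperfusion difference
  signal negative.
* `ε`: additive Gaussian noise, default σ = 4 (baseline SNR 100). At these
  SNRs Gaussian noise is an adequate stand-in for Rician magnitude-MRI
  statistics and keeps every oracle analytic.

Protocol defaults mirror a 1.5 T acquisition: TE 47 ms, TR 1440 ms, 40 time
points, single slice, 96×96 voxels. Ground truth (label map, noise-free
concentration curves, phase indices obtained by applying the detection rules
to the noise-free sampled curves, leakage sign map, TOI set) is returned
with every simulation; output is bit-identical under a fixed seed.

Canonical fixtures: **F1** (null) gives the three tissue classes identical
distributions, so every significant test is a false positive; **F2**
(effect) gives enhancing lesions twice the texture sd (4× variance), a 1.5
index earlier bolus onset (contrast reaches a disrupted lesion slightly
before NAWM) and leakage 600, and non-enhancing lesions a 25% reduced bolus
amplitude (mild hypoperfusion); **F3** (cardiac pair) scales every bolus
amplitude ×1.5 with noise off (see above). Fixtures carry 12 TOI disks of
radius 4 per tissue class on a lesion grid, plus a lesion-free NAWM
reference strip — a scaled-down version of a multi-patient TOI sample,
chosen to keep the 100-seed suites fast while giving the rank-sum tests
12-per-group samples.

## What the phantom does and does not show

Passing tests demonstrate the pipeline's internal correctness and that
*designed* effects of realistic size are recovered: they do not establish
clinical sensitivity. The phantom has no anatomy, no partial-volume mixing,
no motion, no EPI distortion, no Rician noise floor, and its texture field
is spatially white — real lesion texture is correlated and
non-stationary. Lesion/tissue separations in F2 are constructed, so effect
sizes say nothing about real MS lesions.

## Known limitations

* Phases are global per examination (defined on the NAWM reference curve),
  not per voxel; tissues with earlier bolus arrival are averaged over the
  reference-defined intervals.
* The kernel trades SNR against spatial resolution; small lesions lose
  border voxels to the validity band (twice as many for VAVA). The
  kernel-free direct TOI mode avoids this at the cost of pooling the whole
  region into one sample.
* The exact rank-sum mode is limited to `n+m ≤ 12` by enumeration cost;
  beyond that the tie-corrected normal approximation is used.
* DICOM support covers plain single-frame series sorted by
  (AcquisitionTime, InstanceNumber) with an InstanceNumber fallback; vendor
  private tags and enhanced multi-frame objects are out of scope.
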