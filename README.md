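# dtpa — dynamic texture parameter analysis of DSCE-MRI

`dtpa` analyzes the *temporal evolution of image texture* during the passage
of a gadolinium bolus in dynamic susceptibility contrast enhanced (DSCE) MRI.
It is aimed at quantitative characterization of brain tissue whose
microcirculation or blood–brain barrier (BBB) differs from normal-appearing
white matter (NAWM) — the motivating case being enhancing (EL) and
non-enhancing (NEL) multiple-sclerosis lesions — without any pharmacokinetic
perfusion modelling.

## Method

Let `S_k(x)` be the echo-planar image series. The analysis works on
difference images

```
D_k(x) = S_0(x) − S_k(x)
```

where `S_0` is the first steady-state baseline image: `D_k > 0` where the
susceptibility effect of intravascular contrast darkens the signal, and
`D_k < 0` where late T1 enhancement from contrast leaking through a broken
BBB lifts the signal above baseline.

Two multiplicative nuisances are removed against a user-drawn NAWM reference
region: the RF **coil load** (the raw series is scaled so the reference
baseline mean equals `c_ideal`) and the **cardiac output** (the difference
series is scaled so the reference difference-curve area under the curve over
the inflow+outflow window equals `auc_ref = 200`).

The bolus passage is segmented automatically on the reference concentration
curve `C(t) = −(1/TE)·ln(S(t)/S(0))` into four intervals — baseline (BLP),
inflow (IFP, arrival → peak), outflow (OFP, peak → first post-peak minimum)
and reperfusion (RPP) — and all comparisons are made on per-interval time
averages.

Eight time-resolved **texture parameter maps** (TPMs) are computed, six of
them over a sliding `w×w` voxel kernel on `D_k`: the original series (ORIG),
the difference series (DIFF), the local mean (AVER), variance (VARI),
standard deviation (STDEV), skewness (SKEW), excess kurtosis (KURT,
Gaussian → 0) and the variance-of-the-variance (VAVA, a second local-variance
pass over the VARI map — a heterogeneity measure that, unlike VARI, is not an
edge detector).

For every tissue of interest (TOI), every TPM and every interval, six region
statistics (mean, st-dev, variance, variance-of-variance, skewness, kurtosis)
are extracted: 6 statistics × 4 intervals × 3 tissue classes = **72
parameter cells per TPM**, 8 × 72 = **576 possible pairwise tests**. Each
cell is screened with a one-way ANOVA gate (p < 0.05) and, when gated, the
three pairwise two-sided Wilcoxon rank-sum tests (NAWM vs EL, NAWM vs NEL,
NEL vs EL) are run with Benjamini–Hochberg correction. At p = 0.05 a global
null would produce 576 × 0.05 = **28.8** false positives — the yardstick the
counting report prints next to the observed counts.

Two derived surrogate markers grade lesions on a continuous scale:
`ΔTPM-DIFF` (and `ΔTPM-AVER`, `ΔTPM-VAVA`, `ΔTPM-STDEV`, `ΔTPM-VARI`), the
difference of the interval-averaged TOI mean between RPP and IFP. Leakage
pulls the reperfusion difference signal below its inflow level, so ΔTPM-DIFF
decreases monotonically with the amount of BBB leakage.

A seeded synthetic phantom generator (`dtpa.phantom`) produces DSCE series
with per-tissue gamma-variate bolus responses, a cumulative-uptake leakage
term, per-tissue spatial texture and additive noise, together with full
ground truth — it backs every stochastic test in the suite.

## Worked example

```python
import dtpa

config = dtpa.effect_phantom_config(seed=11)     # EL: 4x texture variance + leakage
series, truth = dtpa.simulate_phantom(config)
result = dtpa.run_workflow(
    dtpa.RunConfig(), series=series, tois=truth.tois + [truth.reference_toi]
)
ph = result.phases
print(f"phases: toa={ph.toa} peak={ph.t_peak} min={ph.t_min}")
print(result.counts["counts"])
```

prints

```
phases: toa=9 peak=13 min=21
       BLP  IFP  OFP  RPP  Total
ORIG     6    9    9    9     33
DIFF     2    9    5    3     19
AVER     8   15   17   17     57
VARI     8   14   16   12     50
STDEV    8   14   15   10     47
SKEW     1    9   15   12     37
KURT     4    9    9   10     32
VAVA     8   14   16   15     53
Total   45   93  102   88    328
```

The bolus arrives at time index 9, peaks at 13 and reaches its post-peak
minimum at 21, defining the four intervals. The counts table lists, per TPM
and interval, how many BH-corrected pairwise tests were significant: 328 of
576 possible — far above the 28.8 expected by chance — because this phantom
was built with real tissue differences. The enhancing-lesion leakage is
graded by the Δ-marker: `ΔTPM-DIFF` averages −27.6 in the EL TOIs versus
−15.1 in NAWM (more negative ⇒ more leakage).

The same pipeline runs from the shell:

```
dtpa simulate fixtures/ --seed 0
dtpa run --input fixtures/F2_effect.nii --tois fixtures/F2_effect_labels.nii --out out/
```

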