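# Methods

This note documents the models, conventions and numerical choices behind the
package, and what its synthetic-data validation does and does not show.

## Forward kinetic model

Dynamic tracer uptake in a region is generated by the irreversible
two-tissue compartment model

    dC1/dt = K1·Cp(t) − (k2 + k3)·C1(t)
    dC2/dt = k3·C1(t),        C_T = C1 + C2

with delivery K1 (ml·cm⁻³·min⁻¹), efflux k2 (min⁻¹) and irreversible
trapping k3 (min⁻¹). For the MAO-B tracer, k3 stands for specific binding;
with k3 = 0 the model collapses to the reversible one-tissue model. No
arterial input is measured in the reference-tissue workflow, so the plasma
input Cp is a synthetic bolus: a linear rise to a peak at 1 min followed by
a tri-exponential decay (fractions 0.7/0.2/0.1 at 2.5/0.25/0.02 min⁻¹,
peak 30 kBq/ml). Its exact shape is immaterial to the reference-based
quantification — it cancels between target and reference — which is why the
parameters are plain configuration rather than estimated quantities.

The ODE solution is computed on a fine uniform grid (1 s steps over 60 min)
with the exact one-step exponential-decay update and trapezoidal treatment
of Cp within each step, realised as an IIR filter; this is the recursion
itself, not an approximation to it, and the suite verifies agreement with a
high-accuracy stiff integrator to < 0.5% and invariance to grid refinement
to < 0.1%. All curves are decay-corrected by convention (PET reconstructions
deliver decay-corrected data; the simulator therefore never models isotope
decay).

Frame averaging follows the acquisition contract: the measured value of a
frame is the time-average of the continuous curve over the frame, computed
by trapezoidal quadrature (exact for linear integrands). Measurement noise
is multiplicative Gaussian with per-frame SD cv·value/√(Δᵢ/Δ_max), so longer
frames — which accumulate more counts — are proportionally less noisy. The
law is a simulator convention chosen for its qualitative count-statistics
behaviour; its default cv = 0.05 is a typical frame-level reproducibility
figure for regional PET means.

## Reference-Patlak quantification

The reference region (cerebellar gray matter) itself traps tracer weakly,
which curves the Patlak plot. The measured reference TAC is therefore
corrected by solving the integral equation

    C_ref(t) = C_f(t) + k3_ref · ∫₀ᵗ C_f(τ) dτ,   k3_ref = 0.01 min⁻¹

for the free curve C_f, by forward recursion over frame midpoints with a
trapezoidal cumulative integral. The correction factor 0.01 is treated as a
rate in min⁻¹ (the bare number is conventionally quoted without units) and
is the smallest value that linearises the late plot; the suite checks that
the corrected fit's residual SD is < 1% of the mean plot ordinate and that a
forward-constructed trapped curve round-trips to its free curve within 1%.

The graphical coordinates are x = ∫₀ᵗC_f/C_f (minutes) and y = C_T/C_f. Two
conventions matter and are fixed as follows:

- the cumulative integral runs from injection (t = 0) over *all* frames,
  even though only late frames enter the fit: the integral is a cumulative
  physical quantity. The first segment [0, t₀] uses the first frame value,
  so a constant curve integrates to c·t exactly;
- frame midpoints represent frame time; the 20–60 min fit window is
  inclusive at both bounds; the line fit is unweighted ordinary least
  squares (no weighting is specified for this analysis in the field's usual
  description, and the late frames have comparable durations).

The slope k_I estimates the net uptake rate K1·k3/(k2+k3) normalised by the
reference free distribution volume. Against a brute-force oracle (the secant
of the normalised curves between 200 and 300 min on a fine grid) the
noise-free fit recovers the slope to ≈ 0.1% across k3 = 0.01–0.1 min⁻¹, and
the estimator's bias under cv = 0.05 noise is below 10% for k3 ≥ 0.03.

## ROI pipeline

Late sum images are duration-weighted means of the frames whose midpoints
fall inside the window (PIB 40–60 min, FDG 30–45 min). Regional sampling
averages image values over voxels carrying the region label AND a
gray-matter probability strictly above 0.5. PIB and FDG regional values are
normalised by the pons mean; the global amyloid ratio is the mean of a
configurable cortical composite divided by cerebellar gray matter, positive
strictly above 1.41 (the boundary value classifies negative — the cutoff
source does not resolve the boundary, so the strict convention is fixed here
and in config).

The default atlas has 24 named bilateral regions. The pons is deliberately a
separate reference label rather than a table region: a pons/pons column
would be identically 1 and carry no variance, which the scaling step
correctly rejects. The 24-region list itself is a documented package default
(it includes the 11 regions used in the group statistics); any atlas with
matching names can be substituted.

The feature table is subjects × (24 regions × 3 tracers) = 72 columns,
ordered region-major and tracer-minor (pib, fdg, ded), with a group label
per row.

## Cohort simulator

The simulator's defaults encode the study conditions: group sizes 7 (sAD),
8 (MCI PIB+), 3 (MCI PIB−), 12 (non-carriers), 6 (presymptomatic carriers),
3 (symptomatic carriers); ages drawn from each group's reported mean ± SD;
expected-years-to-onset (EYO) −11.8 ± 8.1 for presymptomatic and 1.9 ± 2.6
for symptomatic carriers. Effect multipliers (per group, applied to regional
baselines) encode the qualitative orderings the analysis is designed to
detect — amyloid: symptomatic 2.10 > sAD 1.90 ≳ MCI PIB+ 1.85 >
presymptomatic 1.40 > non-carriers 1.00 ≳ MCI PIB− 0.96, with no amyloid
effect in hippocampus or cerebellum; metabolism: symptomatic 0.75 < sAD 0.80
< MCI PIB+ 0.84 < presymptomatic 0.93 < MCI PIB− 0.97 < non-carriers 1.00;
astrocytosis (k3 multipliers): presymptomatic 1.55 > MCI PIB+ 1.30 >
symptomatic 1.15 > non-carriers 1.00 > sAD 0.88 > MCI PIB− 0.82. EYO adds a
mild monotone ramp for carriers (amyloid up, metabolism and astrocytosis
down as onset approaches), ±5% at the extremes so group-level orderings are
preserved. Between-subject variation is log-normal (cv 0.08) so positivity
is preserved by construction.

What this validates: that the pipeline recovers orderings and multivariate
structure it is pointed at, at realistic noise levels and sample sizes. What
it does not validate: absolute patient values (not public), spatial
covariance between neighbouring regions, registration/segmentation error,
partial-volume effects, or scanner physics — regional measures are simulated
directly, and the voxel path is exercised only by painting regional values
into a toy atlas.

## PCA and Q²

Columns are mean-centered and scaled to unit variance (SD with n−1).
Components are extracted sequentially by NIPALS with deflation; convergence
is declared when the score vector's change drops below a relative tolerance
(default 1e−12), and the sign is fixed so each loading's largest-magnitude
element is positive. R²X per component is the incremental fraction of the
preprocessed sum of squares explained. On complete data NIPALS agrees with
an SVD to < 1e−6 over hundreds of random matrices; NIPALS is retained
because the cross-validation requires fitting with missing elements, and it
handles a 72-variable × 39-subject table (more variables than observations)
without modification.

Q² uses element-wise deletion cross-validation: matrix elements are assigned
to 7 diagonal-striped deletion groups ((i+j+offset) mod 7; the offset is
rotated deterministically by the seed). For each component and group the
deleted elements are predicted from a component fitted on the remaining
elements (missing-data NIPALS: absent elements are skipped in the score and
loading regressions), PRESS accumulates over the deleted cells, and
Q²ₐ = 1 − PRESSₐ/SSₐ with the cumulative Q² = 1 − Π(PRESSₐ/SSₐ). The scheme
is the long-standing chemometrics default; the exact vendor deletion pattern
is not public, so this choice is documented rather than claimed identical.
Within the CV fits the power iteration can drift arbitrarily slowly inside
a near-degenerate noise eigenspace while the held-out predictions are
already stable, so those fits cap the iteration count and accept the
current component; the complete-data model fit keeps the strict
convergence-or-error contract. Q² separates structure from noise cleanly:
> 0.95 on noiseless rank-1 data, < 0.1 (typically negative) on pure noise.

## Group statistics

Kruskal–Wallis (tie-corrected H, chi-square p with groups−1 df) is applied
per ROI over the four groups with n ≥ 5; all-identical data yields H = 0,
p = 1 rather than an error. Post-hoc Mann–Whitney U reports the
tie-corrected normal-approximation z (no continuity correction, matching
common statistical packages) because the effect size is defined as
r = z/√N; z > 0 means the first-named group tends larger. For untied data an
exact two-sided p is reported alongside and verified against exhaustive
enumeration for all splits with total n ≤ 10. No multiple-testing correction
is applied (by design, matching the analysis convention for these small
exploratory cohorts) — stated here prominently.

Small groups (n < 5) are assessed as individual z-scores against the
non-carrier reference (n−1 SD), abnormal strictly above |z| = 1.645.

The voxelwise layer compares one subject with the five age-nearest controls
(ties broken by smaller id): t = (x_s − mean_c)/(s_c·√(1+1/5)) with df = 4
(the single subject contributes no variance to the pooled estimate),
thresholded one-tailed at p < 0.001 per contrast direction (the SPM
convention for directional contrasts), restricted to the binary gray-matter
mask; zero-variance voxels are excluded and counted, and suprathreshold
voxels are grouped by 26-connectivity.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale by choice: fine grids
of 1 s, the study-sized 39-subject cohort for table-level checks, a
60-per-group variant for rank-correlation assertions, 200 noise replicates
for estimator bias, and exhaustive enumeration up to n = 10. Every random
draw derives from an explicit seed; per-subject streams are split from the
master seed so cohorts are bitwise reproducible.

## Known limitations

- The reference correction assumes a single fixed k3_ref for all subjects;
  no per-subject estimation is attempted (by design).
- Regional measures are simulated independently across regions given the
  group effect; real data have strong spatial covariance, so the synthetic
  R²X/Q² values characterise the pipeline, not the disease.
- The Mann–Whitney normal approximation is used at very small n because the
  effect-size definition requires a z; the exact p is provided for
  inference-critical use.
- NIfTI affines are carried through unmodified; no registration, reslicing,
  smoothing or partial-volume correction is provided.
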