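# multipet

Multi-tracer regional PET analysis for small clinical cohorts, with a
synthetic-data path that makes every stage testable without patient data.

The package targets studies that combine three tracers per subject —
an amyloid ligand (PIB), an astrocytosis marker (the MAO-B ligand
deuterium-L-deprenyl, DED) and a glucose-metabolism tracer (FDG) — across
cohorts such as autosomal dominant Alzheimer's disease families, where
presymptomatic mutation carriers can be compared with non-carriers, MCI
patients and sporadic AD. It implements:

- **Forward kinetics** (`multipet.tac`): an irreversible two-tissue
  compartment model dC₁/dt = K₁·C_p − (k₂+k₃)·C₁, dC₂/dt = k₃·C₁ driven by a
  synthetic bolus input, frame-averaged over the acquisition schedules
  (DED: 4×30 s, 8×60 s, 4×300 s, 3×600 s; PIB: 4×30, 9×60, 3×180, 8×300 s;
  FDG: 1×60, 1×1140, 5×300 s), with a duration-weighted multiplicative noise
  model.
- **Modified reference-Patlak quantification** (`multipet.patlak`): the
  measured cerebellar gray-matter reference curve is corrected for
  irreversible trapping at a fixed rate k₃ᵣ = 0.01 min⁻¹ by solving
  C_ref(t) = C_f(t) + k₃ᵣ·∫₀ᵗ C_f, then y = C_T/C_f is regressed on
  x = ∫₀ᵗC_f/C_f over 20–60 min. The slope k_I is the net tracer binding
  rate; the intercept is the initial distribution volume. Exposed as the
  scikit-learn-style estimator `ReferencePatlak`.
- **ROI plumbing** (`multipet.roi`): late sum-window images (PIB 40–60 min,
  FDG 30–45 min), atlas sampling restricted to a binary gray-matter mask
  (probability > 0.5), pons-normalised uptake ratios, the global
  cortical-to-cerebellar PIB ratio with positivity cutoff 1.41, and the
  subjects × (24 regions × 3 tracers) = 72-variable feature table.
- **NIPALS PCA with Q²** (`multipet.pca`): mean-centering, unit-variance
  scaling, sequential NIPALS with deflation, per-component R²X, and
  cross-validated predictability Q² = 1 − PRESS/SS by element-wise deletion
  over seven diagonal-striped groups. Exposed as `NIPALSPCA`.
- **Nonparametric statistics** (`multipet.stats`): Kruskal–Wallis over 11
  bilateral ROIs, post-hoc Mann–Whitney U with effect size r = z/√N,
  individual z-scores against the non-carrier group (abnormal at
  |z| > 1.645), and a single-subject vs five age-nearest-controls voxelwise
  t contrast at p < 0.001 uncorrected.
- **Cohort simulator** (`multipet.cohort`): group sizes 7/8/3/12/6/3
  (sporadic AD, MCI PIB+, MCI PIB−, non-carriers, presymptomatic and
  symptomatic mutation carriers) with effect multipliers encoding the
  expected orderings: amyloid highest in symptomatic carriers/sAD/MCI PIB+,
  metabolism lowest in symptomatic carriers and sAD, astrocytosis highest in
  presymptomatic carriers.

## Worked example

```python
import numpy as np
from multipet import protocol, tac
from multipet.patlak import ReferencePatlak
from multipet.cohort import simulate_cohort, cohort_feature_table
from multipet.pca import NIPALSPCA, q2_cross_validation
from multipet.roi import feature_matrix

# quantify net DED binding for one simulated region
grid = tac.default_grid_min()
inp = tac.InputFunction()
sched = protocol.FRAME_SCHEDULES["DED"]
target = tac.sample_frames(grid, tac.tissue_tac(tac.KineticParams(0.3, 0.2, 0.05), inp, grid), sched)
ref = tac.sample_frames(grid, tac.tissue_tac(tac.KineticParams(0.3, 0.2, 0.01), inp, grid), sched)
fit = ReferencePatlak(k3_ref=0.01, window=(20, 60)).fit(target, ref)
print(f"slope = {fit.slope_:.4f} /min, intercept = {fit.intercept_:.3f}")

# full synthetic study: cohort -> 72-variable table -> PCA with Q2
table = cohort_feature_table(simulate_cohort(master_seed=1))
X = feature_matrix(table)
model = NIPALSPCA(n_components=2).fit(X)
q2 = q2_cross_validation(X, n_components=2, seed=1)
print(f"R2X(cum) = {model.r2x_cum_[-1]:.2f}, Q2(cum) = {q2.q2_cumulative:.2f}")
```

Output:

```
slope = 0.0420 /min, intercept = 0.842
R2X(cum) = 0.73, Q2(cum) = 0.69
```

The slope 0.042 min⁻¹ is the net trapping rate the Patlak line recovers for a
region simulated with k₃ = 0.05 min⁻¹ (the reference normalisation rescales
it); R²X is the fraction of scaled data variance the two components explain
and Q² its cross-validated counterpart — Q² close to R²X indicates the
group structure in the table is real signal, not overfit.

A command-line surface mirrors the library:
`multipet simulate`, `multipet fit-patlak`, `multipet build-features`,
`multipet pca`, `multipet stats` (see `multipet --help`).

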