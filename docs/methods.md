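# Methods

## Model and procedure

The classification target is a binary subject label (case = 1, control = 0).
Features are region-level supra-threshold voxel counts from per-subject
t-statistic maps aligned to an integer-labeled atlas: for region *r* the
count of voxels with `t >= T`. The comparison is inclusive and one-sided
(positive tail) by default because the underlying contrast asks where
activation is *greater* under high cognitive load; both choices are exposed
(`inclusive=False`, `mode="absolute"`). The default cutoff `T = 3.17`
corresponds to a one-sided tail probability of ~7.6e-4 in the normal limit;
`t_tail_probability` requires explicit degrees of freedom (or `inf`) rather
than guessing a study-specific value.

The classifier is a logistic regression on training-standardized counts with
age and sex appended as covariates. The fitted objective is

    (1/n) * sum_i -log L_i(beta)  +  (alpha/2) * ||beta_slopes||^2

with the intercept unpenalized and `alpha = 1/n_train` by default. The small
default ridge exists to keep coefficients finite under quasi-separation,
which is routine at ~48 training subjects and dozens of features; it is not
meant to shrink meaningfully. The optimizer is a damped Newton (IRLS)
iteration with backtracking line search — deterministic, and converges in a
few dozen iterations even when the data are nearly separable. A seeded
per-sample SGD optimizer is available (`method="sgd"`) for fidelity to
descriptions of gradient-descent training; it is not the default because a
second-order deterministic fit is reproducible and stable at this sample
size. Non-convergence raises an error reporting the final gradient norm;
separation at `alpha = 0` triggers a warning and a fallback ridge of 1/n.

Feature screening has two stages. The Pearson screen computes the
region-by-region correlation matrix over subjects and flags pairs with
`|R| >= 0.9` (absolute value: the direction of a linear dependency is
irrelevant to multicollinearity); it is run three times — training rows,
test rows, combined — and all three reports are emitted. Pair summaries at
descriptive levels (0.7, 0.8, 0.9) use strict `>`, matching how such counts
are usually reported, while the removal rule uses `>=`. Zero-variance
regions get R = 0 off-diagonal and are listed separately rather than
producing NaNs. Recursive feature elimination refits the penalized logistic
learner each round on the surviving training-standardized regions (age/sex
are pinned: included in every fit, never removable) and removes the region
with the smallest absolute coefficient, one per round, recording the full
elimination order; ties break toward the later column, and a constant
feature (coefficient exactly 0 under ridge) is always removed before any
informative one. The default target is half the input regions, exposed as a
flag, since the end-stage region count is a free choice in this design.

Splitting is stratified per class with training count
`round-half-up(ratio * class size)` — at ratio 0.7 with 38 cases and 31
controls this gives 27 + 22 training and 11 + 9 test subjects. The rounding
rule is documented because the test-set size depends on it. The decision
threshold is fixed at `p >= 0.5` (ties classify as case); no threshold
tuning is performed.

Validation:

- `evaluate` reports tp/fn/fp/tn and accuracy, sensitivity, specificity,
  PPV, NPV as percentages, at full precision and in printed style
  (one-decimal truncation). Undefined ratios (zero denominator) are reported
  as `None`, never as 0.
- `subgroup_cv` partitions the test set into k non-overlapping seeded
  subgroups (sizes within 1) and scores the *fixed* model on each; the
  size-weighted subgroup mean identically equals the pooled test accuracy.
- `shuffle_test` permutes labels, redraws a stratified split of the shuffled
  sample, refits the model over the fixed selected-region set, and scores
  the shuffled test rows; the empirical p is the raw exceedance fraction
  (so a printed 11/10,000 reproduces as 0.0011 exactly), with the add-one
  estimate `(k+1)/(n+1)` also reported since the raw ratio can be 0. If no
  exceedance occurs in the first stage, an escalation stage extends the run
  count and the p is recomputed over all runs executed. Refitting without
  re-running feature selection is the default (a `reselect=True` variant
  reruns RFE per shuffle); selection is fixed because the shuffle is meant
  to test the final model's accuracy under exchangeable labels, and because
  per-shuffle RFE is two orders of magnitude costlier. The null
  distribution's mode is computed over the exact attainable discrete
  accuracies (k / test size), ties toward the smaller value.

`solve_confusion` inverts printed metric sets: it enumerates all integer
confusion quadruples with total ≤ `max_n` and keeps those whose metrics
agree with every printed value. A printed one-decimal value is accepted if
it equals either the truncation or the rounding of the full-precision
metric — published tables mix the two conventions (e.g. 66.666…% printed as
66.7 alongside 80.952…% printed as 80.9), and requiring truncation alone
would make one session's metric set unsatisfiable.

## Synthetic cohort generator

The generator emulates the *inputs* to this pipeline, not the MRI physics:
per-subject 3-D t-statistic maps over a shared atlas, for two groups with
optional planted regional differences.

- **Atlas**: an ellipsoidal foreground mask partitioned into `n_regions`
  parcels by nearest-centroid (Voronoi) assignment to seeded random
  centroids — the simultaneous-front limit of region growing. Inside the
  convex mask every parcel is contiguous and contains at least its centroid.
  Default 117 regions on a 24×28×24 grid (~6,600 foreground voxels, ~56 per
  region), RAS+ affine with 2 mm isotropic spacing.
- **Noise**: voxelwise standard Gaussian, optionally smoothed with a
  Gaussian kernel (sigma in voxels; default 1.27 ≈ 6 mm FWHM at 2 mm
  voxels). Smoothing uses toroidal boundary conditions and the field is
  rescaled by the kernel's L2 norm, so the marginal variance is exactly 1 at
  every voxel — this keeps threshold-exceedance probabilities calibrated,
  which reflecting boundaries would break near the mask edge.
- **Planted effects**: calibrated at the level the classifier sees. A
  region's target supra-threshold fraction `p` is imposed by shifting the
  t-mean to `T - sd * Phi^{-1}(1 - p)`, so the expected voxel-exceedance
  fraction equals `p` exactly. Controls sit at the baseline fraction
  (default 0.05) everywhere; cases get `baseline + effect` inside effect
  regions. Background voxels carry pure noise.
- **Covariates**: age uniform on a configurable range (default 25–70 y);
  sex Bernoulli with group-specific male rates defaulting to the published
  cohort's composition (10/38 cases, 19/31 controls), so covariate handling
  is exercised under a realistic sex imbalance.
- **Determinism**: one `numpy` Generator seeded from the config; the same
  config reproduces the cohort bit for bit.

The default planted effect used by the demo pipeline and the power suites is
+0.30 in five scattered regions (cases activate ~35% of region voxels vs the
5% baseline). The magnitude was set by an explicit power analysis at the
default cohort size (69 subjects): the demonstration suites require the
strong-signal regime (detection in ≳9/10 replicates), and +0.2 leaves the
permutation test under-powered at n = 69 while +0.25–0.30 achieves it; 0.30
was fixed with margin and is not revisited. It represents a large, obvious
regional difference — appropriate for a positive-control simulation, not an
estimate of any real-world effect.

What the generator does *not* model: hemodynamics, task timing, motion,
inter-subject anatomical variability, spatially varying noise, and
correlation between regions beyond what the smoothing kernel induces across
parcel borders. Passing tests on this generator therefore demonstrate the
pipeline's statistical machinery (calibration of the permutation null,
recovery of strong planted signals, absence of train/test leakage), not
classification performance on real fMRI data.

## Numerical choices

- Newton fit: gradient tolerance 1e-8 (max-norm), 100 iterations, 1e-12
  jitter on the Hessian diagonal; pipeline-internal refits (RFE rounds,
  shuffle runs) use a 60-iteration budget, ample for these problem sizes.
- Standardization uses population SD (ddof = 0); zero-variance columns get
  scale 1 so a constant feature contributes exactly 0.
- RFE tie-break: later column loses; split rounding: half-up; subgroup CV
  partition: seeded permutation then `array_split`.
- Printed-style metrics truncate (floor) at one decimal; full precision is
  always stored alongside.

## Suite problem sizes

The statistical suites run at the cohort size the design targets (38 + 31
subjects, 117 regions): the null-calibration study uses 200 experiments ×
200 permutations (type-I fraction asserted within [0.02, 0.09]); the power
and recovery study uses 10 seeds with 200 permutations plus a 400-run
escalation stage — enough resolution to call p < 0.05 while keeping the
whole suite a few minutes long. The acceptance script's pipeline run uses
the full 1,000-permutation first stage with 10,000-run escalation.

## Known limitations

- The bundled region-coefficient table is report content for overlap and
  parsing checks; the package never uses those coefficients as model inputs.
- `ratio_sweep` flags overfitting by the mean train-test gap only; with
  very small test sets (90:10 on n ≈ 69) single-run accuracies are coarse.
- The permutation p is slightly anti-conservative when feature selection is
  not rerun per shuffle (the observed accuracy's selection saw the true
  labels); the measured type-I fraction at 0.05 is ~0.07. `reselect=True`
  removes this at substantial cost.
- Subject metadata travels in JSON/TSV sidecars next to the NIfTI files; a
  bare NIfTI without a sidecar loads with a warning and placeholder
  covariates.
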