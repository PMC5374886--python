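# Methods

## Analysis model

`netgof` quantifies the spatial correspondence between a patient cohort's
control-referenced Z-score maps and labelled intrinsic-connectivity-network
(ICN) templates.

**SUVR.** Uptake volumes are divided by the unweighted arithmetic mean of
the voxels inside a reference-region mask.  The output has mean exactly 1
over the reference, is invariant to global rescaling of the input, and the
operation is idempotent.  The pipeline order is SUVR first, then smoothing,
then Z-maps.

**Smoothing.** Separable Gaussian filtering at a stated FWHM (default
8 mm), with per-axis sigma in voxels = FWHM / (2·√(2·ln 2)) / voxel size.
Boundary handling replicates edge values so constant fields are fixed
points; this avoids artificial edge attenuation on the small grids used in
simulation.

**Z-score maps.** The control group defines voxelwise mean and *sample* SD
images (denominator n−1; the control set is a sample, and the choice only
rescales Z by √(n/(n−1))).  Voxels with SD ≤ `sd_floor` (default 1e−6 in
map units) are excluded via an explicit validity mask, never clamped and
never encoded as sentinel numbers; all downstream statistics respect the
mask.  Z-scores built from a finite control sample are inflated on average
by E[σ/ŝ] (≈ 1.050 at 17 controls, ≈ 1.008 at 100), a property of the
Z-map definition itself; the recovery experiments account for it via their
standard errors rather than by altering the published formula.

**Network scores.** For a subject Z-map and an atlas at level 7 or 17:
*mean Z* is the unweighted mean over valid voxels of the template;
*GOF* is mean Z inside minus the mean Z of valid cortical voxels outside,
where "cortical voxels outside" means voxels carrying a different nonzero
label.  Background voxels never dilute the outside mean — the GOF contrast
is within-cortex by construction.  Both metrics satisfy the exact algebraic
identity GOF_k = (mean_k − cortex_mean) · N/(N − N_k), which the test suite
verifies against a brute-force voxel loop at 1e−12.

**Group inference.** Per network × metric, a one-sample t-test against 0
with sample SD and the exact t CDF (no normal approximation).  The
Bonferroni threshold is α_fw/K with K the number of networks at the level;
decisions use the unrounded threshold, displays round to 3 decimals
(0.05/7 → "0.007", 0.05/17 → "0.003").  Tables are rendered at 3 decimals.
Networks are ranked by descending group-mean Z with ties broken by
ascending id.

**Cross-cohort correlation.** Pearson r between two mean Z-maps across
cortical-mask voxels.  The p-value from the t transform with
df = n_voxels − 2 assumes independent voxels; smoothed maps violate this
badly, so the p is reported only as a flagged reference and r is the
headline quantity.

## Synthetic cohorts

The generator emulates the study design the package analyses, on a
32×32×32 grid of 2 mm voxels by default: a central spherical "cortex"
partitioned into 7 or 17 contiguous Voronoi parcels around seeded points,
and a disjoint "cerebellar" reference blob in the background (a
configurable fraction of background voxels nearest the grid origin).
A master seed spawns one substream per subject, so cohorts are
bit-reproducible and individual subjects can be regenerated in isolation.

Voxel model for subject s at voxel v with label k:

    value(v) = baseline + a_s·[v ∈ cortex] + g_s·δ_k·σ_c + ε_v

* ε_v ~ N(0, noise_sd²) i.i.d. (noise_sd default 0.1 SUVR units);
* a_s ~ N(0, global_sd²) is a per-subject global *cortical* offset
  (default 0.2), the between-subject variability in cortical binding that
  normalization to a cerebellar reference cannot remove; it produces the
  between-subject Z-score SD floor of ≈ 0.9 control-SD units seen in real
  cohort tables;
* σ_c = √(noise_sd² + global_sd²) is the true cortical control SD, so the
  patient elevation δ_k is parameterized directly in control-SD units and
  the expected patient Z in network k is severity·δ_k (making recovery
  tests sharp);
* g_s = severity·floor + Gamma(mean = severity·(1−floor), sd = subject_sd)
  is the subject's pathology severity: right-skewed (a few high-burden
  patients among many low-burden ones, as in prodromal cohorts), with a
  small floor (default 0.05) encoding that every included patient carries
  some pathology, and E[g_s] = severity exactly.  Defaults severity = 1,
  subject_sd = 1 reproduce the coefficient of variation (≈ 1) of published
  severe-cohort score tables; a milder replication cohort is modelled by
  severity ≈ 0.3 with the same absolute subject_sd, which reproduces the
  published pattern of strong spatial correlation without any network
  surviving the corrected threshold.

Setting `subject_sd = 0` and `global_sd = 0` reduces the generator to a
plain i.i.d.-noise model (value = baseline + δ_k·noise_sd·[patient] + ε);
the sharp analytic recovery tests use that configuration, with standard
errors that include the control-reference sampling terms shared across
subjects (control-mean error and the voxelwise 1/ŝ fluctuation, with
E[(σ/ŝ)²] = ν/(ν−2) and Var(σ/ŝ) from the χ distribution).

The default effect profiles are the canonical severity gradients of the
motivating application: at level 7, DAN 3.2 > VIS 3.1 > DMN 2.9 > LIM 2.7
> FPN 2.2 > VAN 2.1 > SMN 0.9 (control-SD units); at level 17 the
corresponding 17-subnetwork profile to one decimal.

**What the generator does not emulate.** Gaussian i.i.d. voxel noise has
no spatial autocorrelation (an optional smoothing step in the pipeline
induces it downstream, but the raw noise field is white); parcels are
convex-ish Voronoi cells rather than distributed, bilateral networks;
there is no scanner- or site-dependent structure, no partial-volume
effects, no off-target binding, and no spatial spreading dynamics of
pathology.  Passing recovery tests therefore demonstrates correctness of
the estimators and pipeline plumbing under a known generative model — not
that real acquisitions satisfy that model.

## Experiment design choices

* The recovery and ranking experiments run the pipeline *without*
  smoothing, keeping E[mean Z per network] analytically equal to
  severity·δ_k.  Smoothing rescales the control SD and would re-scale Z by
  a boundary-dependent factor, blurring the recovery target.
* The cross-cohort experiment runs *with* 8 mm smoothing, matching the
  real pipeline; smoothing suppresses the white-noise component of the
  mean maps and makes r reflect the shared network pattern.
* Problem sizes: 32³ grids, 7 networks of ~1000 voxels each,
  17 + 27 and 19 + 16 subjects for the two cohorts, and 100 replicates
  for the rank-recovery rate — small enough to run the entire suite in
  seconds while keeping every per-network voxel count in the hundreds.

## Numerical choices

* Sample SD everywhere (ddof = 1); exact t CDF p-values; the Pearson r is
  clipped into [−1, 1] against rounding.
* Means over voxel subsets use float64 pairwise summation; for a constant
  map the GOF is exactly 0.0 for dyadic constants and below 1e−12
  otherwise.
* Mismatched Z-map validity masks are intersected with a warning in
  `mean_zmap`; degenerate inputs (empty reference, zero SD, single
  control, all-equal values) raise `ValueError` rather than returning
  sentinel numbers.
* Voronoi parcel seeding redraws until every parcel has ≥ 8 voxels
  (practically immediate at the default sizes).

## Open definitional points

* The exact cortical mask of the original analyses is not recoverable
  from their description; this package defines cortex as the atlas's
  nonzero-label support, and documents GOF's "outside" set as
  other-network voxels.
* Whether Z computation was masked to gray matter upstream of network
  sampling is likewise unstated; Z is computed wherever the control SD is
  valid, and the atlas selects voxels.
* The uptake-window difference between cohorts (80–120 vs 80–100 min) is
  upstream of this package: inputs are taken as already time-averaged.

## Limitations

Raw-data quantities of the motivating study — actual mean Z-map
topographies, the exact cross-cohort r, and cohort-specific means/SDs —
require the original scans and are not reproducible here; the package
covers them indirectly through summary-statistic recomputation and the
synthetic recovery experiments.  The cross-cohort p-value is
anti-conservative by construction and should not be interpreted beyond
"r is large".  No resampling, registration, surface-based analysis, 4D
support, covariate-adjusted (W-score) maps, or probabilistic templates.
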