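# Methods

This note documents the models, parameter choices and known limitations
of the package, in the order of the processing chain.

## Diffusion tensor estimation

Signals follow the single-shell monoexponential model
S = S0·exp(−b gᵀDg) with b in s/mm² and unit gradient directions g in
world (RAS) coordinates.  The tensor is estimated per voxel from the
log-linearised model by ordinary least squares followed by one weighted
pass with weights equal to the squared predicted signals — the standard
correction for the heteroscedasticity introduced by the log transform,
and the behaviour of common DTIFIT-class tools.  An iterative nonlinear
fit was deliberately avoided: at the SNR regimes of interest the WLS
solution is indistinguishable in practice and has no convergence
failure modes.

Numerical rules:

- voxels with any non-positive signal drop those volumes; fewer than 7
  usable volumes makes the voxel unfittable (zero tensor, flagged, and
  removed from the effective mask);
- a gradient scheme must span the 6-dimensional quadratic-form space
  (≥ 6 non-collinear directions), else fitting is refused outright;
- negative eigenvalues after the fit are clamped to zero with the voxel
  flagged, keeping FA/MD defined while preserving QC visibility.

FA is √(3/2)·‖λ−λ̄‖/‖λ‖ (defined as 0 for zero tensors) and MD is
trace(D)/3.  The default simulated acquisition is 5 b0 volumes plus 61
directions at b = 1000 s/mm² (a quasi-uniform Fibonacci-sphere spread);
4 b0 / 64-direction dialects are accepted equally.  Simulated noise is
Rician by default (two independent Gaussian channels in quadrature),
Gaussian optionally.

Axis semantics: all volumes are reoriented to RAS on load, so that
x = left–right, y = anterior–posterior, z = head–foot.  Narrative
descriptions of the ALPS geometry in the literature are not fully
consistent about which letter names which fibre system; this package
fixes the convention the index formula itself implies — projection
fibres dominant along z, association fibres along y, perivascular
component along x — and the denominator is accordingly
mean(Dyy_proj, Dzz_assoc).  On-disk tensor components are stored in
voxel axes (FSL-style, order Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) and rotated
into the new frame when a file needs reorientation; b-vectors are
interpreted in world coordinates and therefore unchanged.

## ROIs and the ALPS index

ROIs are spheres defined in world millimetres (default radius 5 mm).  A
voxel belongs to a sphere when its center point lies within the radius,
boundary included — a deterministic, resolution-independent rule.  Axis
diffusivities are arithmetic means of the tensor diagonal over in-mask
voxels; non-finite voxels are excluded and flagged.  The per-hemisphere
index is mean(Dxx_proj, Dxx_assoc)/mean(Dyy_proj, Dzz_assoc) and the
bilateral index is the exact average of the two hemispheres.

Published template-space ROI coordinates for this analysis live in
supplementary material not reproduced here, so ROI centers are
mandatory configuration inputs; the shipped defaults are defined in the
synthetic phantom's own coordinate frame.  Spatial normalisation is out
of scope: inputs are declared co-registered and ROIs are interpreted in
the input's world space.

Manual placement inspection is replaced by an automated proxy with
three configurable checks per ROI: mean FA ≥ 0.15 (fibre tissue, not
CSF/background), ≥ 50% of principal eigenvectors within a 30° cone of
the expected fibre axis (projection → z, association → y), and ≥ 10
voxels.  A QC failure never suppresses the index; the result carries
the fail status and reason codes so callers can exclude the subject, as
the manual workflow would.

## Synthetic phantoms

The phantom emulates periventricular geometry on a 64×48×48 grid of
1 mm isotropic voxels: per hemisphere a projection-fibre slab
(|x| ∈ [3, 15] mm, tensor diag(λ⊥+ε, λ⊥, λ∥)) and a lateral
association-fibre slab (|x| ∈ [16, 28] mm, diag(λ⊥+ε, λ∥, λ⊥)),
both restricted to |y|, |z| ≤ 10 mm, in an isotropic background
(0.8×10⁻³ mm²/s).  Defaults λ∥ = 1.4×10⁻³, λ⊥ = 0.4×10⁻³ mm²/s are
healthy-white-matter-like values; ε is the perivascular increment on
Dxx, so the ground-truth index has the closed form (λ⊥+ε)/λ⊥, and the
default ε = 0.12×10⁻³ places it at 1.30, the healthy cohort level.
Optional Gaussian noise on the diagonal entries is followed by
projection back onto the PSD cone.  What the phantom does not model:
anatomy, partial-volume/CSF contamination, off-diagonal fibre
dispersion, scanner artifacts — phantom-based tests therefore validate
the computational pipeline, not robustness to real-data confounds.

## Synthetic cohorts

The cross-sectional generator draws eight groups — young (n=50) and old
(n=33) non-carriers; presymptomatic C9orf72/GRN/MAPT (68/88/43);
symptomatic (44/31/17) — with the published estimated marginal means of
the ALPS index per group (1.32/1.29; 1.28/1.32/1.28; 1.19/1.24/1.21).
Only EMM standard errors are published, so subject-level SDs are
recovered as SE·√n per group.  Age, sex and education distributions
follow the published per-group summaries; imaging site is a uniform
5-level categorical and plasma-analysis site a 3-level one (the true
multi-site structure is not public; these are declared assumptions).

Outcomes are generated directly from the association slopes the fitted
models are expected to recover: CDR-FTLD = 2.0 − 1.16·ALPS + N(0, 0.5)
in carriers; ln NfL and ln GFAP linear in ALPS with slopes −0.28 and
−0.10 (noise 0.5/0.4, missingness 24%/37% mirroring the published
assay availability); years to expected onset linear in ALPS with slope
−9.94 (noise SD 10) in presymptomatic carriers, small positive values
past onset for symptomatic ones.  This makes the association models
correctly specified, which is what the parameter-recovery tests
require; the cost is that stage separation in severity is carried by
the ALPS group means rather than by an explicit stage effect, so the
simulated severity distributions are flatter than clinical reality.
CDR-FTLD is generated on a continuous latent scale and reported both
raw and rounded to the instrument's 0.5 step (floored at 0); statistics
default to the latent value.

At the published dispersions, the old-NC-versus-symptomatic comparison
has only moderate power (~50–60% at FDR-corrected α = 0.05 at these
group sizes), so tests assert its detection as a rate over replicate
cohorts rather than on a single draw.

The longitudinal generator gives each carrier 1–6 visits at 1-year
spacing with count probabilities (102, 75, 50, 40, 12, 3)/282 — the
exact per-count frequencies implied by the published cumulative
follow-up counts, reproducing ≈ 660 evaluations in expectation.
Severity at time t is baseline + (stratum slope + subject random
slope)·t + random intercept + residual noise, floored at 0 on the
instrument scale (the latent column is kept).  Stratum slopes default
to 0.20 / 0.05 / −0.01 CDR-FTLD units/year for low / average / high
baseline ALPS; random-effect SDs (intercept 0.15, slope 0.04, residual
0.12) are this package's assumptions, chosen to give realistic
within-subject scatter relative to the 0.5 instrument step.

## Statistics

- Group comparisons: OLS of the outcome on group plus covariates (age,
  sex, imaging site by default).  EMMs are evaluated at the covariate
  means (continuous) and observed marginal proportions (categorical);
  the published analyses report EMMs without stating the reference
  grid, so this common default was fixed.  Only the two pre-declared
  contrast families are ever tested — 3 stage-level and 9
  mutation-by-stage pairs — with Benjamini–Hochberg adjustment strictly
  within each family, never pooled across analyses.
- Associations: OLS with the stated covariates; plasma outcomes are
  natural-log transformed (non-positive values are an error naming the
  subjects); plasma models add the analysis-site covariate.
  Complete-case analysis per model.
- Stratification: Z = (ALPS − NC mean)/NC SD with the pooled sample SD
  over all non-carriers; Z > 1 is high, Z < −1 low, boundaries fall in
  "average" because the extreme classes are defined by strict
  inequalities.
- Progression: linear mixed model with fixed effects time, stratum,
  stratum×time, age, sex, site and baseline severity, and a random
  intercept and slope per subject; REML estimation with Wald z
  inference for coefficients, slopes (time + interaction term) and
  their pairwise contrasts, plus a joint Wald χ² for the interaction.
  Wald z was chosen over a denominator-df approximation because the
  reference analyses do not state one and z is portable across
  ecosystems.
- Degenerate inputs: rank-deficient designs raise an error naming the
  collinear columns; all-single-visit data refuse the mixed model;
  non-convergence is flagged on the result rather than raised.

One property worth noting: the BH step-up map is not idempotent on
general monotone vectors (re-adjusting an adjusted vector can increase
it further); only tied/flat adjusted vectors are fixed points, and the
tests assert exactly that plus monotonicity of re-adjustment.

## Determinism and problem sizes

All generators take explicit seeds; a single global pipeline seed is
expanded into per-stage seeds via `numpy.random.SeedSequence(global,
stage_id)` (documented stage ids, values < 2³¹), so stages are
independently reproducible and re-running a configured pipeline
rewrites byte-identical outputs.  Model fitting itself contains no
randomness.

Simulation-based checks use: 20 phantom seeds for the noisy closed-form
check; 100 replicate cohorts for cross-sectional slope coverage and 500
for null calibration; 6 replicates for mixed-model slope coverage in
the unit suite, one defaults-generated dataset plus 200 equal-slope
null replicates in the acceptance suite.  These sizes give binomial
standard errors comfortably below the asserted margins while keeping
the default test run a few minutes long.

## Known limitations

- The ALPS index is a proxy; nothing here models actual perivascular
  flow physics.
- No denoising, eddy/motion correction or registration: inputs are
  assumed preprocessed and co-registered.
- The automated placement QC is a reproducible stand-in for expert
  visual inspection, not a validated replica of it.
- Synthetic cohorts reproduce published group-level moments and
  association slopes, not the joint distribution of real GENFI data;
  passing recovery tests demonstrates correctness of the estimators
  under the stated generative model, not robustness to model
  misspecification.
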