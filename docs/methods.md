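# Methods

## Overview

`aslcbf` implements one coherent analysis chain: single-compartment
quantification of pcASL perfusion, local-regression partial-volume correction,
regional/whole-brain extraction, and a random-intercept/random-slope mixed
model for the association between baseline perfusion and annual MMSE change.
Because the package ships no patient data, a synthetic phantom and a
generative cohort simulator provide ground truth for every stage; their
defaults define the study conditions all tests run under.

## Quantification

CBF is a scalar multiple of ΔS/S₀:

CBF = u · λ (1 − e^(−T_SAT/T_1GM)) e^(w/T_1B) / (2 T_1B (1 − e^(−τ/T_1B)) ε) · ΔS/S₀

Defaults (w = 2.0 s, τ = 1.5 s, λ = 0.9 mL/g, ε = 0.6, T_1B = 1.4 s,
T_SAT = 2.0 s, T_1GM = 1.2 s) give a factor of ≈ 1.6547 × 10⁴ per unit ΔS/S₀
with the unit conversion u = 6000 from mL/g/s to mL/100 g/min. The formula
in λ and seconds yields mL/g/s; u is required for perfusion to land in the
conventional tens of mL/100 g/min. ε folds label efficiency and
background-suppression losses into one constant; no transit-time or
multi-delay modelling is attempted. Negative values (noise) are preserved —
clipping would bias ROI means — and voxels outside the brain mask are zero
and excluded from all statistics. A non-positive S₀ inside the mask is a
hard error that reports the offending voxel count.

## Partial-volume correction

At each brain voxel the uncorrected CBF values u in a Gaussian-weighted
neighbourhood are modelled as u ≈ P_GM·c_GM + P_WM·c_WM (no intercept, CSF
perfusion assumed zero) and solved by weighted least squares. The kernel has
FWHM 9.5 mm (σ = FWHM/2.3548 ≈ 4.034 mm), is converted to voxel units per
axis (anisotropy respected), truncated at 3σ per axis, and normalized.
Truncation is per-axis (a box support) so the stencil is an exact outer
product of 1-D kernels; the regression then factors into five separable
convolutions (the Gaussian-filtered products P_GM², P_GM P_WM, P_WM²,
P_GM·u, P_WM·u) plus a closed-form 2×2 solve per voxel. This is
algebraically identical to looping a weighted regression over stencils — the
test suite verifies voxel-by-voxel agreement with exactly that brute-force
implementation — but runs in seconds on realistic grids.

Numerical choices:

- The stencil is clipped at the volume boundary (zero padding); weight
  renormalization is immaterial because a common weight scale cancels in the
  least-squares solution.
- A voxel is *valid* when the local 2×2 normal matrix is positive definite
  with condition number ≤ 1e8. Elsewhere the design is effectively
  single-tissue and the dominant-tissue ratio estimate
  Σw·u / Σw·P_dom is recorded as a fallback. The exported cortical map uses
  the regression estimate at valid voxels and the fallback at GM-dominant
  degenerate voxels, which makes the correction an exact identity on pure
  gray matter.
- Cortical reporting applies a configurable guard P_GM ≥ 0.05 at the centre
  voxel; PVC summaries weight by P_GM, so low-GM voxels are negligible either
  way.
- Corrected cortical ROI means are Σ P_GM·c_GM / Σ P_GM over valid ROI
  voxels; invalid voxels are excluded, an all-zero GM ROI is an error.

## Regional extraction

Uncorrected regional means are plain voxel averages over the label map
(frontal, parietal, PRCPCC, temporal, occipital); the whole-brain value
averages every voxel with nonzero tissue fraction, CSF included — which is
why it sits well below cortical gray-matter perfusion. A region absent from
a label map is reported as missing, never as zero.

## The phantom

Geometry is three concentric ellipsoids — CSF core (ρ < 0.22 of the brain
radius), white-matter shell (to ρ = 0.62), gray-matter shell (to ρ = 1) —
with smoothstep partial-volume ramps two voxels wide, on a default 48³ grid
of 1.7 mm isotropic voxels. Five azimuthal 72° sectors of the GM shell stand
in for the named cortical regions; GM-dominant voxels (P_GM ≥ 0.5) carry
sector labels, all other brain tissue is "other". Ground truth obeys the
two-tissue mixing law exactly: true_cbf = P_GM·c_GM(region) + P_WM·c_WM.

Default regional GM perfusion (18.7, 23.9, 30.2, 21.8, 29.1 mL/100 g/min for
frontal/parietal/PRCPCC/temporal/occipital) is calibrated to the magnitudes
reported for Alzheimer's-dementia memory-clinic cohorts, and the geometry
keeps the uncorrected regional means within ~4 % of these values (mixing
with WM and the brain edge accounts for the gap). White matter defaults to
20 mL/100 g/min — below the cortical values so the correction has signal to
separate — and "other" gray matter to 25.

The forward ASL simulation inverts the quantification equation (ΔS =
true_cbf/f · S₀ with S₀ = 1000 on the brain, noise-free), so
simulate → quantify is the identity to machine precision. Gaussian noise with
SD = noise_sd_fraction × mean|ΔS| (default 0.1) is added to ΔS only; keeping
S₀ noise-free makes the propagated CBF noise exactly Gaussian with a
predictable SD, which the tests check against a single-voxel Monte-Carlo
oracle.

What the phantom deliberately does not emulate: head anatomy, k-space/spiral
readout effects, motion, transit-time heterogeneity, spatially correlated
noise. Passing tests therefore demonstrate correctness of the arithmetic and
the estimators under the stated noise model, not robustness to scanner
artefacts.

## The cohort simulator

Each of n = 88 (default) subjects receives independent baseline covariates
matching a typical Alzheimer's-dementia clinic population: age ~ N(65, 7²),
sex Bernoulli(½), education on the 7-level Verhage scale (discretized
N(5, 1)), normalized gray-matter volume N(715.8, 44.6²) mL, medial temporal
atrophy as the mean of two 0–4 ratings (0.5 steps, median 1.5), Fazekas 0–3,
and zero-inflated Poisson microbleed/lacune counts with median 0. Baseline
CBF measures are drawn independently per measure from normal distributions
with the regional means/SDs above (truncated positive); when the pipeline
runs end-to-end the means are replaced by the values actually measured on
the phantom.

Visits: counts uniform on [2, 8]; baseline at t = 0 and gaps uniform in
[0.7, 1.3] × the mean interval (default 1 year). MMSE follows the exact
generative twin of the analysis model with defaults β₀ = 22, β_t = −2.11,
β_c = −0.42, β_ct = −0.50 (per SD decrease of the driving measure,
whole-brain by default), zero covariate effects, and dispersions
σ_u0 = 3, σ_u1 = 1.5, σ_ε = 1.5 MMSE points — the dispersions are package
choices of plausible magnitude, since fitted variance components for such
cohorts are rarely published. Scores are continuous by default; optional
clamping rounds to integers in [0, 30] but biases slope recovery near the
floor, hence the default is off.

## Mixed-model analysis

Inclusion requires ≥ 2 MMSE scores spanning ≥ 1 year. The predictor is the
baseline value of one CBF column, standardized with the sample SD (n−1) over
the included, complete-case sample and inverted: z = (mean − x)/SD, one unit
of z = one SD *decrease*. Estimation is REML (ML available) via
`statsmodels` MixedLM with an unstructured 2×2 random-effects covariance;
p-values are Wald against a normal reference. Design choices where the
convention is genuinely open:

- REML and the unstructured covariance mirror the defaults of the major
  statistical packages for this model class.
- Covariates enter as main effects only (no covariate×time terms).
- Missing covariate values drop the subject from that model (complete-case,
  logged); covariates that are constant in the sample, or that exceed the
  subject-level design rank (possible in very small samples), are dropped
  with a log message rather than producing a singular fit.
- Non-convergence is flagged on the result object, never raised; the fit is
  retried across optimizers (L-BFGS, CG, Powell) first.
- The unadjusted annual change fits the same random-effects structure with
  time as the only fixed effect.

Reported grids show β ± SE for the predictor main effect ("estimated baseline
MMSE" per SD decrease) and the predictor×time interaction ("estimated annual
change"), with a star at p ≤ 0.05 and a dagger at p ≤ 0.06 (thresholds
configurable).

## Pipeline and reproducibility

`run_pipeline` executes phantom → simulate → quantify → PVC → extract →
cohort → inclusion → fits, writing NIfTI volumes (uncompressed, so repeated
runs are byte-identical), CSVs with fixed schemas, a text report and a
provenance log. One top-level seed is split with `numpy` SeedSequence into
independent per-stage seeds (< 2³¹); the cohort's CBF distributions are
centred on the phantom-measured regional values. Default problem sizes — a
48³ phantom and 88 subjects, with 200 replicate cohorts for the recovery
study — were chosen so each stage's sampling error is small relative to the
tolerances being checked while the whole chain runs in minutes on one CPU.

## Known limitations

- The phantom's five "regions" are azimuthal sectors, not anatomy; regional
  differences are encoded purely through the ground-truth perfusion values.
- CBF measures are drawn independently across regions within subject; real
  regional perfusion is strongly correlated.
- The PVC noise model is correct for i.i.d. Gaussian ΔS noise; spatially
  correlated noise would correlate neighbouring regression estimates.
- Wald inference at n = 88 is adequate (the suite verifies SE calibration to
  within 20 %) but small-sample REML degrees-of-freedom corrections
  (Satterthwaite/Kenward-Roger) are not implemented.
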