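# aslcbf

Perfusion MRI analysis for longitudinal memory-clinic studies: voxelwise
cerebral blood flow (CBF) quantification from pseudo-continuous arterial spin
labelling (pcASL), kernel-regression partial-volume correction (PVC), regional
perfusion extraction, and linear mixed models relating baseline perfusion to
the rate of cognitive decline. A synthetic brain phantom and a cohort
simulator make the whole chain testable end to end without any patient data.

## Who this is for

Researchers analysing ASL perfusion in dementia cohorts who want a single,
validated pipeline from the raw ASL difference image to a fitted
decline model — and a ground-truth simulation framework to check every stage
of that pipeline.

## The models

**Quantification.** With the labelled-minus-control difference image ΔS and
the proton-density reference S₀, single-compartment CBF is

```
CBF = λ (1 − e^(−T_SAT/T_1GM)) · e^(w/T_1B) / (2 T_1B (1 − e^(−τ/T_1B)) ε) · ΔS/S₀
```

with post-label delay w = 2.0 s, labelling time τ = 1.5 s, partition
coefficient λ = 0.9 mL/g, labelling efficiency ε = 0.8·0.75 (label ×
background suppression), T₁ of blood 1.4 s, saturation-recovery time 2.0 s
and T₁ correction 1.2 s. A factor of 6000 converts mL/g/s to mL/100 g/min.

**Partial-volume correction.** At each voxel, CBF values in a 3-D Gaussian
neighbourhood (FWHM 9.5 mm) are regressed on the local gray- and white-matter
partial-volume fractions (no intercept, CSF perfusion 0), giving pure-tissue
perfusion maps; cortical summaries weight the corrected gray-matter map by
the gray-matter fraction.

**Longitudinal model.** Subjects with ≥ 2 MMSE scores spanning ≥ 1 year enter
the analysis. Baseline CBF is standardized and inverted (z per SD *decrease*)
and MMSE is modelled with a random intercept and random slope on time:

```
MMSE_ij = β₀ + β_c z_i + β_t t_ij + β_ct z_i t_ij + Σ γ_k x_ik + u_0i + u_1i t_ij + ε_ij
```

β_ct is the headline quantity: the extra annual MMSE change per SD lower
baseline perfusion. Covariate set "model1" adjusts for age, sex, education;
"model2" adds normalized gray-matter volume, medial temporal atrophy,
white-matter hyperintensities, microbleeds and lacunes.

## Worked example

```python
from aslcbf import (PhantomConfig, build_phantom, simulate_asl, KineticParams,
                    quantify_cbf, pvc_regress, regional_means,
                    CohortConfig, simulate_cohort, apply_inclusion,
                    CBFDeclineModel, annual_change)

truth = build_phantom(PhantomConfig())               # 48³ multi-tissue phantom
stack = simulate_asl(truth, KineticParams(), noise_sd_fraction=0.1, seed=1)
cbf = quantify_cbf(stack, KineticParams())
pvc = pvc_regress(cbf, truth.pve_gm, truth.pve_wm)
summary = regional_means(cbf, truth.region_labels, pvc, truth.pve_gm)
print(f"parietal uncorrected {summary.uncorrected['parietal']:.1f}, "
      f"PVC cortical {summary.pvc_cortical['parietal']:.1f} mL/100 g/min")

cohort = apply_inclusion(simulate_cohort(CohortConfig(seed=1)))
print(annual_change(cohort).summary())
print(CBFDeclineModel.from_dataframe(cohort, covariates="model1").fit().summary())
```

prints

```
parietal uncorrected 23.1, PVC cortical 24.0 mL/100 g/min
Mixed model: MMSE decline
subjects: 84   observations: 436   converged: True
term                        beta       SE        p
Intercept                 21.805    0.385        0
time                      -1.957    0.182 6.57e-27
variance components: intercept 11.260, slope 2.412, covariance 0.105, residual 2.038
Mixed model: MMSE decline ~ cbf_whole_brain (covariates: model1)
subjects: 84   observations: 436   converged: True
term                        beta       SE        p
Intercept                 16.855    4.501  0.00018
cbf_z                     -0.503    0.390    0.197
time                      -1.951    0.176 1.86e-28
cbf_z:time                -0.461    0.176  0.00875
age_years                  0.076    0.065    0.238
sex                        0.383    0.785    0.626
education                 -0.032    0.400    0.937
variance components: intercept 11.319, slope 2.237, covariance -0.127, residual 2.036
```

The parietal uncorrected mean (23.1 mL/100 g/min) is the plain voxel average
over the parietal label; the PVC value is the gray-matter-fraction-weighted
mean of the corrected cortical map, slightly higher because mixed voxels are
no longer diluted by CSF. The `time` coefficient (−1.96 points/year) is this
cohort's mean annual MMSE change, and `cbf_z:time` (−0.46 ± 0.18) says each
SD of lower baseline whole-brain CBF costs about half an MMSE point per year
— close to the generating value of −0.50 used by the simulator.

The same chain runs from the shell:

```
aslcbf run-all --out results_dir --seed 1
```

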