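# compfmri

Univariate and multivariate Bayesian tests of **age-related functional
compensation** in task fMRI, with a synthetic-cohort generator for
ground-truth validation.

## The problem

In healthy ageing, older adults often show *extra* task activation.  Is it
compensation — additional recruitment that carries task-relevant
information and supports performance — or mere inefficiency?  This package
implements a two-stage answer for blocked-design studies:

1. **Univariate criteria.**  Per participant, a prewhitened GLM estimates
   the Hard−Easy contrast of a demanding task.  At the group level,
   `contrast ~ age * performance + sex` (all predictors standardised) is
   fit at every voxel; inference uses threshold-free cluster enhancement
   (TFCE) with max-statistic permutation correction and a t > 1.97
   threshold.  Candidate compensation regions are connected clusters where
   *both* age and performance have positive unique effects.  ROI-level
   regressions are repeated after dividing the contrast by the
   resting-state fluctuation amplitude (RSFA), a vascular scaling that
   removes age effects of cerebrovascular, rather than neural, origin.
2. **Multivariate Bayesian (MVB) decoding.**  For each candidate region, a
   hierarchical Bayesian model with a sparse spatial prior decodes the
   Hard>Easy design contrast from multivoxel patterns, scored by the
   variational free energy F — here an exact log model evidence.  The key
   comparison is Δ = F(joint model: region + size-matched multiple-demand
   voxels) − F(MDN-only model).  Δ > 3 nats (Bayes factor ≈ 20, since
   ln 20 ≈ 3) is a *boost*: the region carries non-redundant task
   information.  Compensation predicts that the probability of a boost
   increases with age, tested by logistic regression with sex and the
   region's mean activation as covariates.  Decoding reliability is
   established against 20 phase-shuffled targets (amplitude spectrum
   preserved, phases randomised); participants whose joint model does not
   beat this null by ≥ 3 nats are dropped.

Every stage is exercised end-to-end on simulated cohorts with recorded
ground truth (age-dependent behavioural decline, regional effect slopes,
AR(1)-plus-coherent noise, age-dependent vascular gain, and an
age-modulated multivoxel pattern orthogonal to the region's mean
response).  See `docs/methods.md` for the full model and its limits.

## Worked example

Run a small synthetic study end to end (about half a minute):

```python
from compfmri.pipeline import RunConfig, run_pipeline
from compfmri.simulate import SimulationConfig, RegionSpec

specs = [
    RegionSpec(label="mdn", n_voxels=27, base_contrast=0.8, perf_slope=0.1,
               vascular_age_slope=-0.3),
    RegionSpec(label="cuneal", n_voxels=27, base_contrast=0.5, age_slope=1.2,
               perf_slope=1.2, interaction_slope=0.1, unique_info_base=0.15,
               unique_info_age_slope=0.15, vascular_age_slope=-0.3,
               subject_sd=0.05),
]
sim = SimulationConfig(n_participants=30, grid_shape=(10, 9, 9),
                       region_specs=specs, seed=0)
config = RunConfig(simulation=sim, seed=42, n_perm=200, tfce_n_steps=25,
                   n_shuffles=5)
run_pipeline(config, "demo")
print(open("demo/summary.txt").read())
```

The summary starts:

```
Participants included: 30
Excluded at chance/no-response: 0
Intersection ROIs: comproi_1 (26 voxels)
ROI comproi_1: unreliable decoding dropped 8; categories {'boost': 22, 'ambiguous': 7, 'reduction': 1}
```

Reading the outputs:

* `behaviour_regression.tsv` — performance declines with age
  (standardised slope −0.67, t = −4.66, p < 0.001; the generator's true
  slope is −0.7).
* `table1.tsv` — the discovered 26-voxel ROI (26 of the 27 simulated
  "cuneal" voxels) shows positive unique effects of age (estimate 0.97,
  t = 8.6) and performance (1.21, t = 10.8) that persist after RSFA
  scaling (1.06 and 1.21) — the univariate compensation signature, and
  evidence it is not vascular.
* `table2.tsv` — per-participant MVB model comparisons: 22 boosts, 7
  ambiguous, 1 reduction (8 participants failed the phase-shuffle
  reliability check and were dropped).  With one reduction present the
  boost model is an ordered logit; the age odds ratio here is 1.85
  (n.s. at this small n — the calibrated power study lives in the
  acceptance script).

The same run is available from the shell:

```bash
compfmri all --config config.yaml --seed 42 --out demo
compfmri report --out demo
```

with subcommands `simulate`, `glm`, `group`, `mvb`, `compare`, `report`
for individual (resumable, checksummed) stages.

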