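# Methods

`compfmri` implements and validates an analysis for detecting age-related
functional compensation in blocked task fMRI: univariate age x performance
criteria with vascular adjustment, plus a multivariate Bayesian (MVB)
decoding test of whether a candidate region carries task information beyond
the generically task-responsive multiple demand network (MDN).  Because the
method's claims are about what the *analysis* can infer, the package pairs
every stage with a synthetic-cohort generator whose ground truth is known,
and all validation statements below are computed by the test suite or by
`scripts/acceptance.py` — nothing is quoted from external data.

## Study model

A cohort of adults (ages uniform over 19–87 by default) performs a
problem-solving task in eight alternating 30-s easy/hard blocks inside a
150-scan, TR 2 s run.  The 60 s of run time not covered by blocks is rest,
placed half at the start and half at the end by default (configurable).
Behavioural performance is scored as (hard correct − hard incorrect plus
easy correct − easy incorrect)/2; participants whose overall proportion
correct falls below 0.5 are excluded as at-chance, and covariates are
z-scored over the included cohort.

## Synthetic-data generator

The generator (`compfmri.simulate`) draws, per participant:

* **Behavioural counts.**  A latent standardised performance trait declines
  linearly with standardised age (default −0.7 per SD; with the default
  trial budgets this yields R² ≈ 0.5 for the age regression, a strong
  lifespan decline).  The trait shifts per-condition success probabilities
  and counts are binomial over fixed budgets (32 easy, 16 hard trials).
  The binomial sampling variance is folded into the latent noise budget so
  the realised standardised age slope matches the configured value in
  expectation; with `performance_sd = 0` counts are deterministic
  (noise-free contract).
* **BOLD.**  Regions are disjoint cuboids on a small 3D grid (default
  20×20×20 at 3 mm; validation studies use smaller grids, stated below).
  Each region voxel responds to hard blocks with amplitude
  `gain_vascular × (c·g_v + u·p_v)` in percent of the 100-unit baseline:
  `c` is the participant's regional Hard−Easy contrast (base + age,
  performance and interaction slopes per SD, plus a participant-level
  residual, default SD 0.15); `g_v` is a fixed per-region voxel gain
  profile (mean 1, SD 0.3) giving the region a stable multivoxel response
  architecture; `p_v` is a per-participant random pattern projected
  orthogonal to both the constant and `g_v` and normalised to unit RMS, so
  it has zero spatial mean (it survives MVB mean removal) and cannot move
  the region average; its amplitude `u` ("unique information") is
  `unique_info_base + unique_info_age_slope · z_age`.  Responses are
  boxcars convolved with the canonical HRF.
* **Noise.**  Stationary AR(1) noise per voxel (marginal SD 1% of
  baseline, lag-1 coefficient 0.3) plus a *coherent* AR(1) series shared by
  all voxels of a region (default 1.5%).  The coherent term emulates
  physiological noise and is essential for the decoding analyses: with
  purely independent voxel noise, adding any voxels to a decoding model
  raises the evidence by tens of nats simply because independent noise
  averages away, and the boost comparison would measure voxel count rather
  than unique information.  With the default amplitudes the joint-vs-MDN
  evidence difference for a region with `u = 0` is centred in the
  ambiguous band.
* **Vascular state.**  A per-participant regional vascular gain
  `1 + vascular_age_slope · z_age + noise` multiplies the BOLD response
  and is also (with voxel noise) the participant's RSFA map, floored at a
  small positive value.  This makes "vascular age effect without neural
  age effect" simulable, which is the scenario the RSFA scaling step must
  neutralise.

What the generator does **not** emulate: realistic anatomy, motion,
slice-timing, drift beyond the cosine band, non-Gaussian physiology,
spatially smooth noise, or trial-level behaviour.  Passing tests therefore
show the *analysis machinery* is correct and calibrated under the model's
assumptions, not that real data meet those assumptions.

## First-level GLM

Condition regressors are 30-s boxcars convolved with the canonical
double-gamma HRF (response delay 6 s, undershoot delay 16 s, dispersions 1,
undershoot ratio 1/6, 32-s support) built at 16 microtime bins per TR and
sampled at mid-TR.  Optional motion covariates are filtered identically to
the data.  An orthonormal discrete cosine set with
`K = floor(2·T/128 + 1)` columns (including the constant) high-pass filters
at 1/128 Hz.  Data are grand-mean scaled to 100.  The error is modelled as
AR(1)-plus-white noise; its three hyperparameters are estimated by
restricted maximum likelihood over a pool of task-responsive voxels
(omnibus-F selected, with a most-responsive-32 fallback), profiling the two
variances analytically in the eigenbasis of the projected AR correlation at
each candidate AR coefficient (grid 0–0.95 step 0.1 plus a local
refinement).  The implied error correlation prewhitens model and data and
ordinary least squares yields per-voxel betas; the carried-forward quantity
is the Hard−Easy contrast of parameter estimates.  The cosine basis enters
the whitened model as columns, which is algebraically equivalent to
projecting it out of both sides.  With zero residual variance (noise-free
simulations) whitening is skipped.

## Group univariate analysis

Per-voxel multiple regression of the contrast maps on
`[1, z_age, z_perf, z_sex, z_age·z_perf]` estimates age and performance
effects simultaneously.  Voxel-wise inference uses threshold-free cluster
enhancement (E = 0.5, H = 2, dh = max/100 by default, 26-connectivity)
with a max-statistic permutation null (default 2000 permutations) built by
Freedman–Lane residual permutation of the tested term.  A voxel is
significant when its family-wise corrected p < 0.05 *and* its t exceeds
1.97 (the conjunction).  Candidate compensation ROIs are the connected
components of the intersection of the positive age and positive
performance significance masks.  ROI-level regressions repeat the model on
the ROI-mean contrast, raw and RSFA-scaled (voxel-wise division by the
RSFA map, with non-positive RSFA voxels dropped and logged), with a
Bonferroni alpha of 0.05/number-of-ROIs.  Two-sided p values throughout.

## MVB decoding

The decoding target is the whitened Hard>Easy contrast of the design,
residualised against the confound space (motion + cosine set); features are
the whitened, filtered ROI voxel series minus the across-voxel mean at each
scan.  The model is `target = features·w + noise` with a sparse spatial
prior: each voxel is its own pattern, and prior weight variances are
grouped into covariance components.  Hyperparameters (noise variance plus
one variance per component) are optimised by Fisher-scoring ReML on the log
scale with Levenberg damping, working in voxel space via the Woodbury
identity (O(v³) per iteration), to convergence |ΔF| < 1e−6 nats or 128
iterations.  Because the model is linear-Gaussian, the maximised restricted
likelihood *is* the log evidence for the fitted hyperparameters; it is
checked against direct numerical maximisation of the closed-form Gaussian
evidence to 1e−3 nats.  The greedy search starts from one all-voxel
component; step k ranks voxels by squared posterior weight and adds a
component over the top 2^−k fraction, accepting while the free energy
increases (max 8 steps, stop on first decrease or on a duplicate subset).

Reliability: the target is phase-shuffled (random Fourier phases, DC and
Nyquist untouched, amplitude spectrum exact) 20 times, re-residualised
against the confounds, and fully refit; decoding is reliable when the true
log evidence exceeds the shuffled mean by ≥ 3 nats (a Bayes factor of
about 20, since ln 20 ≈ 3).

## Compensation tests

For each candidate ROI, an equally sized set of the most activated MDN
voxels (largest group Hard>Easy t, ties broken by voxel index) forms the
matched reference.  The joint model (ROI + matched MDN voxels) is compared
with the MDN-only model: Δ = log-evidence difference, categorised as boost
(Δ > 3), ambiguous (−3 ≤ Δ ≤ 3; boundaries inclusive) or reduction
(Δ < −3).  Group inference is a logistic regression of boost (vs
ambiguous) on standardised age with sex and the ROI's mean univariate
activation (raw contrast) as covariates; odds ratios are exponentiated
estimates.  When reductions occur (possible in simulation), an ordered
logit over reduction < ambiguous < boost is used instead; on perfect
separation the model falls back to an L2-penalised fit with the separation
flagged and no p values reported.  The spread measure is the standard
deviation (ddof = 0) of posterior weights from the ROI-only model,
regressed on the same covariates.

## Validation studies and problem sizes

Run by `tests/test_acceptance.py` and `scripts/acceptance.py`:

1. **Threshold analytics** — exp(3) ≈ 20.09, i.e. the 3-nat criterion is a
   Bayes factor of ~20.
2. **Free energy vs oracle** — 100 random single-component problems
   (≤ 20 voxels, 24–48 scans); max |F − oracle| < 1e−3 nats.
3. **TFCE & FWE** — brute-force threshold-sum equality on 5×5×5 maps; the
   permutation test's family-wise error on 100 pure-noise cohorts (n = 24,
   8×8×8 grid, 200 permutations) within 0.05 ± 0.05.
4. **Slope recovery** — one n = 200 cohort (10×8×8 grid): configured age,
   performance and interaction slopes of ROI activation recovered within
   2 SE, raw and RSFA-scaled; an n = 300 vascular-confound cohort shows
   the spurious raw age slope attenuated by more than half (in practice
   ~90%) after RSFA scaling.
5. **End-to-end detection** — 50 cohorts (n = 70, two 32-voxel regions,
   12×8×8 grid) with unique-information age slope 0.10: a significant
   positive age effect on boost likelihood (z > 1.96) in ≥ 80% of
   cohorts; 25 null cohorts (slope 0) at approximately the nominal rate.
   The reliability filter is bypassed and generative region masks are used
   in this study (ROI discovery and the shuffle null are validated
   separately); cohort size, voxel counts and grids are the package's
   validation choices.

## Numerical choices and edge cases

* All randomness derives from explicit integer seeds through
  `numpy.random.SeedSequence`; per-participant/per-purpose streams are
  keyed by CRC32 of stable string labels, so cohorts are bit-reproducible.
* Log-hyperparameters are clipped to ±32; a component whose variance hits
  the lower bound is effectively pruned.
* TFCE thresholds are integer multiples of dh with a 1e−12 comparison
  tolerance so the map maximum is never dropped by float accumulation.
* Permutation p values use the add-one estimator (b+1)/(m+1) and are
  therefore never zero.
* Matched-MDN selection and intersection-ROI labelling break ties by flat
  voxel index, making ROI definitions deterministic.
* `weight_spread` uses the population SD; scaling all weights by a
  constant scales the spread by the same constant.

## Known limitations

* Pooled (not voxel-wise) AR estimation; spatially varying autocorrelation
  is not modelled.
* Only the sparse MVB prior is implemented (no smooth/compact pattern
  sets, no searchlight, no cross-validated accuracy).
* The boost comparison inherits the method's SNR sensitivity: a region can
  boost evidence through mean-response redistribution under spatial mean
  removal.  The simulation bounds this channel with coherent noise, and
  the group model controls mean univariate activation, mirroring the
  analysis this package implements; the channel is not eliminated.
* Cross-sectional inference only; nothing here distinguishes compensation
  from lifelong individual differences.
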