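# Methods

This note documents the models, conventions and numerical choices behind
`ankle-ssm`, and what the synthetic-data tests do and do not establish
about real radiographic data.

## Shape representation and alignment

A configuration is 68 ordered 2-D landmarks in mm on a lateral ankle view
(distal tibia, talus, calcaneus, navicular). The per-bone point
assignment is configurable; the default split (17 / 21 / 22 / 8) is a
stylized placeholder — published 68-point schemes do not document their
per-bone counts, so nothing downstream depends on it beyond figure
polylines.

**Laterality.** Left and right ankles are pooled in one model. A pooled
Procrustes/PCA is only geometrically coherent in a common chirality, so
left configurations are reflected about their centroid's vertical axis
before alignment. Reflection about the centroid is an isometry: centroid
size and all inter-landmark distances are preserved exactly.

**Full Procrustes.** Generalized Procrustes analysis centers every
configuration, scales it to unit centroid size (root-sum-of-squared
distances from the centroid), and iterates: rotate each shape onto the
consensus by the SVD-optimal (Kabsch) rotation with the determinant
repaired to +1 (reflections are never fitted — laterality is handled
upstream), recompute the consensus as the coordinate-wise mean,
re-center and re-normalize it to unit size. Convergence is the
root-mean-square change of the consensus, default tolerance 1e-8, max 100
iterations (non-convergence warns and reports the final change rather
than failing silently). The total Procrustes sum of squares is recorded
per iteration and is non-increasing. Scale removal means the model
describes *shape*: relative size differences between bones within the
composite remain, overall size does not.

Aligned coordinates are analyzed directly, without projection into the
Procrustes tangent space. Shape variation in radiographic cohorts of one
joint is small (here, Procrustes distances ≲ 0.1), where the curvature
correction is far below the other conventions' effects; the choice is
declared rather than inferred from any reference software.

## Point-distribution model

PCA uses the SVD of the centered (n × 136) aligned shape matrix with the
1/(n−1) covariance divisor, so standardized scores have unit sample
variance under the same convention. Eigenvector signs are fixed
deterministically (largest-magnitude component positive) so figures and
regression signs are reproducible. At most min(n−1, 136) modes are
non-null; reconstruction from all non-null modes is exact to numerical
precision.

**Retention.** The rule is applied in two steps: first the smallest
leading set of modes whose cumulative variance fraction reaches 0.80,
then removal of any member explaining less than 0.01 individually. The
two conditions are stated without an order in the convention this
implements; applying the cumulative rule first can retain a set whose
post-filter cumulative fraction dips below 0.80, which is logged. If the
≥ 1 % modes cannot jointly reach 80 %, all of them are returned with a
warning.

**Scores and synthesis.** Scores are projections of (shape − mean) onto
the basis, divided by √λ_k by default so regression coefficients read
"per SD of shape mode" (raw scores are available by flag; the per-SD
convention matches presenting modes as mean ± k·SD outlines, and a
sensitivity analysis with raw scores only rescales the coefficients).
Mode-shape synthesis is mean + k·√λ·φ; figures draw the mean (solid),
+SD (dashed) and −SD (dotted) outlines as polylines within each bone
group.

## Association models

Logistic regression by IRLS with step-halving on the deviance;
convergence is max-gradient ≤ 1e-10. Separation is detected by the
coefficient-divergence heuristic (|β| > 30 with a non-vanishing
gradient) and raised as an explicit error, as is a rank-deficient design
(the collinear columns are named via pivoted QR).

Inference uses the cluster sandwich B·M·B with B the inverse observed
information and M the sum of outer products of per-cluster score sums,
clusters being participants (two ankles of one person), scaled by the
small-sample factor G/(G−1) — the convention of maximum-likelihood
cluster variance in the major survey packages; no correction is a flag.
With every row its own cluster the estimator reduces to HC0 × n/(n−1).
Confidence intervals are Wald, exp(β ± 1.96·SE); tables exclude the
intercept and flag CIs excluding 1. No multiple-testing adjustment is
made across modes; reports note this.

Two standard model sets are provided: injury on all retained mode scores
(model 1: clustering only; model 2: plus age, BMI, race, sex, KLG,
symptoms), and race on all retained mode scores.

## Repeatability

Placement distances are Euclidean, in the original mm coordinates before
any Procrustes scaling, because the 1 / 1.5 / 2 mm thresholds are
physical distances; "within" is inclusive (≤). Score agreement uses
ICC(2,1) — two-way random effects, absolute agreement, single measure —
because readers are treated as a random sample of trained readers and
single readings are analyzed; the CI is the McGraw–Wong F-based interval.
With subject variance σ²_b and reading-error variance σ²_e the estimand
is σ²_b/(σ²_b + σ²_e), which the closed-form tests target.

## Synthetic cohort generator

The generator defines the study conditions for all recovery tests:

- **Template**: deterministic parametric outlines for the four bones,
  ≈ 113 × 98 mm extent, minimum inter-bone gap > 2 mm. It is stylized,
  not anatomically fitted: tests concern algebra and inference, not
  anatomy.
- **True modes**: low-order polynomial displacement fields of the
  template coordinates with seeded Gaussian coefficients, projected
  orthogonal to the four similarity directions (translations,
  infinitesimal rotation, scaling) and QR-orthonormalized.
- **Cohort structure** (defaults): 200 participants, 10 % bilateral,
  race prevalence 0.67, covariate distributions matching a community
  cohort of older adults (age 71 ± 7.8, BMI 30.3 ± 5.6, 29 % male, 67 %
  KLG 1, 18 % symptomatic); 19 true modes whose mm SDs are sized so that,
  over 0.5 mm digitization noise, the fitted spectrum resembles a
  radiographic cohort (leading mode near 16 %, ≈ 80 % in the leading
  modes). Nuisance transforms: rotation ± 15°, translation ± 20 mm,
  log-scale ± 0.1.
- **Scores**: ankle score z = √ρ·z_person + √(1−ρ)·z_ankle gives
  exchangeable within-person correlation ρ (default 0.9); the white
  group's mode-1 mean is shifted by δ (default 0.8 SD).
- **Injury**: ankle-level Bernoulli with log-odds
  intercept + Σβ_k z_k + γ·race (defaults: β on modes 1, 6, 13, 19 of
  ±0.34…0.65, γ = 1.1, intercept −0.75 for ≈ 50 % prevalence, the 1:1
  case-control regime). The two ankles' draws share a Gaussian-copula
  latent (correlation defaulting to ρ), so each ankle's *marginal*
  probability is exactly the logistic value while within-person outcome
  dependence persists beyond the modeled scores. This term is essential:
  if the only within-person coupling were the shared score component, the
  likelihood would remain correctly specified given the regressors and
  naive ML standard errors would be consistent — cluster-robust inference
  would have nothing to fix. Real bilateral data share unmeasured
  person-level influences, which the latent term emulates.
- **Repeat readings**: i.i.d. isotropic Gaussian placement noise per
  landmark. Distances between a clean and a perturbed reading are
  Rayleigh(sd); between two independently perturbed readings,
  Rayleigh(sd·√2).

Everything is deterministic under the spec's seed.

**What passing tests show — and don't.** Recovery, coverage and
confounding tests certify the estimators under the generator's
assumptions: Gaussian scores, exchangeable within-person correlation,
logistic outcome, isotropic noise, exact landmark correspondence. Real
radiographs add digitization bias, positioning differences,
non-Gaussian shape tails and reader drift, none of which the generator
emulates; passing tests validate the machinery, not any anatomical claim.

## Problem sizes in tests and acceptance runs

Simulation experiments are sized as the smallest designs that make their
estimands sharp: 200 replicates of ≈ 300-ankle cohorts for effect
recovery and coverage, 500 replicates of fully bilateral 150-participant
cohorts (ρ = 0.9) for the naive-vs-robust contrast, 50 seeds for the
confounding direction check, 20 seeds × 500 subjects for ICC
calibration. The recovery experiment uses an 8-mode generator (four
effect modes with per-SD ORs 1.5 / 0.65 / 1.6 / 0.55 and four null
modes): with ~20 regressors at n = 300 the ordinary logistic-MLE
small-sample bias away from zero is itself of order 10 % and would
dominate the comparison, so the nuisance dimension is kept small enough
that the measured error reflects the estimator, not that textbook bias.

## Known limitations

- 2-D lateral-view shape only; no 3-D alignment, no missing-landmark
  estimation, no sliding semilandmarks.
- No GEE, mixed-effects or Firth-penalized alternatives to the
  cluster-robust logistic model.
- The bone-group point assignment and the template are stylized.
- Tangent-space projection is not applied before PCA (see above).
- No multiple-testing adjustment across modes, by design.
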