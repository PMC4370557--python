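# Methods

This note records the models, estimators and numerical choices behind
`rewardlight`, and what the synthetic-data experiments do and do not
establish.

## Decoding model and solver

The classifier is a linear soft-margin SVM in the primal
parameterisation f(w) = (λ/2)‖w‖² + (1/n)Σ max{0, 1 − yᵢ⟨xᵢ, w⟩} with
λ = 1/(nC); C rescales the loss exactly as in the standard C-form, so
the two parameterisations share their minimisers.  It is solved by
Pegasos-style stochastic sub-gradient descent: at iteration t one
uniformly sampled training example estimates a sub-gradient and a step
of size η_t = 1/(λt) is taken.  Choices:

- **Reported iterate.**  The average of the iterates over the last half
  of the run.  Suffix averaging removes most of the stochastic
  oscillation of the final iterates; with T = 1.5×10⁶ iterations the
  objective of the averaged iterate is within ~10⁻⁴ relative of the
  exact optimum on random instances (n ≤ 50, d ≤ 30), comfortably inside
  the 10⁻³ contract checked against liblinear in the acceptance suite.
- **Projection.**  The optional projection onto the ball of radius
  1/√λ from the original algorithm is off by default (flag available);
  it is not needed for convergence and is rarely used in practice.
- **Intercept (SVC).**  A constant-1 feature appended to the data, i.e.
  a regularised bias.  With ±1 labels and near-balanced groups the
  target mean is zero and this choice is benign; the unbiased variant
  (`use_bias=False`) reproduces the pure primal form and is what the
  solver-oracle equivalence tests use.
- **Intercept (SVR).**  The training-fold target mean is absorbed as an
  *unregularised* intercept before fitting, and the solver fits
  residuals (a regularised residual-bias feature remains).  This follows
  the convention of standard SVR implementations, and it matters: with a
  regularised bias and raw symptom scores (mean ≈ 20), the cheapest way
  for the solver to produce mean-level predictions is through the mean
  *feature* direction, which in pattern-carrying data encodes pattern
  expression — null models trained on permuted scores would then still
  "predict" the true scores, destroying the permutation null.  With
  fold-mean absorption the null behaves correctly (chance ρ centred
  slightly below zero).
- **Iteration budgets.**  The default budget is
  min(⌈20/(λ·ε)⌉, 100 000) with ε = 10⁻³.  Map-level runs (searchlight,
  permutation nulls) use explicit budgets of 200–500 steps per fold:
  at those scales the decoding decision, not the exact objective value,
  is the quantity of interest, and the permutation null is computed with
  the identical budget, so the inference is internally consistent at any
  budget.  The solver-oracle tests use 1.5×10⁶ steps.
- **Determinism.**  All solver randomness comes from an in-kernel
  splitmix64 generator seeded per (permutation index, voxel index, fold)
  from the master seed.  Maps are therefore bit-reproducible and
  independent of the order in which voxels are processed.
- **Tie rule.**  A decision value of exactly zero predicts the positive
  class (patients).

## Searchlight and cross-validation

Sphere membership is inclusive: all integer offsets with Euclidean norm
≤ diameter/2 in voxel units (123 offsets at diameter 6, 33 at diameter
4, 7 at diameter 2).  Spheres are clipped at the grid boundary rather
than padded, and a sphere is used whenever its center is in the analysis
mask; the regression searchlight additionally intersects spheres with
the ROI.  Anisotropic grids are rejected rather than silently
mishandled.  Cross-validation is strictly leave-one-subject-out; the
43-vs-44 training imbalance is left as is (the bias it induces is small
and alternates sides across folds).  Voxels whose sphere contains a
non-finite value are skipped and flagged.  The LOOCV chance level is
slightly *below* 50%: leaving a subject out makes the opposite class the
training majority, biasing the prediction against the held-out subject —
visible in the chance-accuracy summaries (mean ≈ 47–48%).

## Permutation inference

One global label permutation per iteration, shared across all voxels
(spatial coherence of the null maps); the identity permutation is
excluded, and requesting more permutations than distinct non-identity
arrangements is an error.  Null predictions are scored against the
permuted labels (full exchangeability; scoring against the true labels
is available behind a flag).  The empirical p-value is the plus-one
estimator p = (1 + #{null ≥ obs})/(P + 1), right-tailed; its floor is
1/(P+1), so P = 10 000 cannot produce p < 10⁻⁴.  Because the accuracy
statistic takes only N+1 discrete values and ties count toward "≥",
these p-values are **valid but conservative** (empirically
P(p ≤ 0.05) ≈ 0.043 at the nominal 0.05 on pure-null cohorts); their
distribution is correspondingly super-uniform rather than exactly
uniform, which any sufficiently powerful goodness-of-fit test against a
continuous uniform will detect.  FDR control is Benjamini–Hochberg
step-up (inclusive threshold); cluster extent filtering uses
18-connectivity by default (6 and 26 available) with an inclusive
minimum size.

The SVR null re-runs the full LOOCV searchlight with one random
reassignment of patient indices per iteration, patched per fold so that
each training set carries exactly the training patients' own scores,
reassigned — the held-out patient's true score never enters training.
Predictions of null models are evaluated against the true scores, so the
chance ρ distribution is centred slightly below zero (the null training
mean excludes the held-out score); a one-sided (right-tailed) empirical
p is used for ρ.

## Univariate baseline

The t map is the pooled-variance two-sample t, oriented
controls − patients (the reported direction of the group difference).
The ROC map records, per voxel, the maximum *in-sample* accuracy over
all cut-points between sorted distinct values (±∞ sentinels, both
decision directions); it deliberately upper-bounds single-voxel
classification and is therefore optimistically biased, increasingly so
at small n — which is why the scaled-down demo can show ROC peaks above
the cross-validated searchlight peak while the study-scale recovery
experiment shows the multivariate peak above the ROC peak on average.
ROC-map p-values come from the same label-permutation scheme as the
searchlight (no parametric null exists for an in-sample maximum).
McNemar's test uses the continuity-corrected statistic by default (raw
variant available) on the paired per-subject correctness of the two
approaches at each one's peak voxel; zero discordant pairs yield an
explicit degenerate result.

## Synthetic cohorts

The generator emulates the statistical structure of a two-group
reward-anticipation contrast study; all defaults are a single place to
read the emulated conditions:

| parameter | default | meaning |
|---|---|---|
| n_per_group | 44 | group sizes of the emulated cohort |
| voxel_size_mm | 3 | isotropic resampled grid |
| smoothing_fwhm | 8 mm | acquisition-style smoothing, applied after effect injection; SD = FWHM/(2√(2 ln 2)) |
| univariate_shift | 0.5 | ROI mean difference, controls above patients |
| pattern_amplitude | 1.0 | scale of the distributed pattern contribution |
| expression_sd | 1.0 | subject-level SD of pattern expression (group means ±1) |
| noise_sd_control / patient | 1.2 / 0.8 | group noise SDs (controls more variable) |
| skewness / kurtosis_excess | 0 / 0 | noise shape, via a power-method (Fleishman) transform |
| symptom intercept/slope/noise | 22 / 3 / 3 | PANSS-negative-scale coupling; slope 3 with noise 3 and unit expression SD gives population Pearson r ≈ 0.71 (Spearman ≈ 0.69) |

Design choices made where the generative model was genuinely open:

- **Pattern model.**  Each ROI gets a fixed random weight vector,
  exactly zero-mean across ROI voxels (so a pure pattern is invisible to
  the ROI-mean contrast), tapered by a Gaussian envelope toward the ROI
  boundary — regional effects are strongest at the region core, and the
  taper keeps the information peak inside the ROI after smoothing.
  Subjects express the pattern with strength drawn from group-specific
  Gaussians (means ±1, SD `expression_sd`).  The separation-to-SD ratio
  of expression sets a decodability ceiling (≈ Φ(1) ≈ 84% at the default
  unit SD); the parameter-recovery experiments use expression_sd = 0.75
  to plant an effect strong enough for ≥80% peak accuracy.
- **Noise shape.**  Skewness/kurtosis are realised by a cubic
  power-method transform of Gaussian noise, solved numerically to hit
  the target moments (verified within 5% in tests); the shaped noise is
  applied to the control group, the group whose distribution the
  variance-asymmetry simulation varies.
- **Symptom scores** exist for patients only, as the regression analysis
  uses the patient group alone.

What the synthetic experiments show — and what they do not: they
establish that the implementation recovers planted effects of known
location and strength, that its permutation inference is calibrated
under a true null, and that the sensitivity/specificity trade-off tracks
group variance differences.  They do not establish performance on real
fMRI data: real contrast maps have spatially structured, non-stationary
noise, anatomically irregular ROIs, registration error and
between-subject anatomical variability, none of which are modelled
(smoothness here is nominal 8 mm FWHM on a stationary Gaussian
background).

## Scaled problem sizes

Desk-scale runs use reduced but structurally faithful sizes chosen once:
demo grid 20×20×12 with 2×22 subjects and 199 permutations; null
calibration on 16×16×10 with 2×20 subjects, a 560-voxel mask and 199
permutations; recovery experiments on 18×18×14 (44 per group, 20 seeds)
and 16×16×10 (44 patients).  The study-scale 10 000 permutations is a
configuration value, not a code path: `PermutationConfig(n_perm=10000)`
runs unchanged, just longer.

## Known limitations

- The per-voxel decoding statistic is a discrete accuracy; with small
  cohorts the empirical p-values are conservative near the working
  threshold (see above), which costs some power but never validity.
- The demo's 22-patient SVR is underpowered: its peak ρ varies widely
  across seeds.  The quantitative recovery claim (peak ρ within ±0.15 of
  the planted 0.7) holds at the emulated study size of 44 patients.
- The Pegasos iteration budget at map scale (200–500 steps) yields a
  stochastic, not exact, decision rule; observed and null maps share the
  budget, so inference remains exchangeable, but absolute accuracies can
  differ slightly from a fully converged SVM's.
- Cluster peaks are reported from unsmoothed accuracy maps; no spatial
  smoothing is applied to statistic maps before peak finding.
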