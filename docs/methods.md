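# Methods

This note documents the models, defaults and numerical choices behind
gccscreen, what the synthetic generator does and does not emulate, and the
known limitations.

## Cohort and descriptive surface

A cohort is one row per postmenopausal woman: age, ten continuous
metabolic biomarkers and five reproductive factors, with NaN as the
explicit missing marker.  Descriptives follow the conventional screening
write-up: per-age-stratum mean/SD/n (default strata 41–50, 51–65, >65
years, configurable), a one-way ANOVA and Levene test across strata per
biomarker, and a Lilliefors-corrected Kolmogorov–Smirnov normality test
per biomarker (the reference normal has sample-estimated mean and SD, so
the plain KS table would be anticonservative).  Frequency tables report
category counts with percentages denominated by the full cohort size
— the convention used in published tables — while each factor's own
non-missing denominator is reported alongside, since item-level
missingness can make the factors' totals differ.

Undefined statistics (a stratum with fewer than two values, a
zero-variance column) are reported as NaN, never raised, so a degenerate
subgroup cannot crash a batch run.

The sample-size helper implements N = Z²_{α/2}·P(1−P)/ε² with half-up
rounding: at 95% confidence, ε = 0.05, P = 0.5 the raw value is 384.16,
and half-up reproduces the conventionally quoted 384 (a ceiling rule would
give 385).

Biomarker redundancy is summarised by the pairwise-complete Pearson
correlation matrix and average-linkage agglomeration under the distance
1 − |r|.  Absolute correlation is deliberate: the clustering's purpose is
redundancy detection, and a marker that tracks the rest negatively (HDL-C)
is just as redundant as one that tracks them positively.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
calibrated to the published marginal summaries:

* **Marginals.** Each biomarker j is Gaussian with the published total
  mean and SD (e.g. BMI 22.54 ± 2.91 kg/m², FPG 4.88 ± 0.90 mmol/L).
* **Latent factor.** One standardized metabolic-health factor L induces
  all cross-biomarker correlation:
  x_j = μ_j + σ_j(λ_j·g_j(L) + √(1−λ_j²)·e_j).  Default loadings are 0.7
  (−0.7 for HDL-C), so under the identity link corr(x_i, x_j) = λ_iλ_j
  ≈ 0.49.  g_j is standardized within the sample so the configured SDs
  are preserved under any link.
* **Nonlinearity.** The "saturating" option uses per-biomarker links
  g_j(L) = tanh(2.5·(L − c_j)) with centres evenly spaced on [−1.2, 1.2].
  Distinct centres are essential: a link shared by all markers would leave
  the data on a straight line (the scalar tanh(L) simply replaces L as the
  common factor), whereas per-marker saturation bends the one-dimensional
  manifold into a curve — the regime where a nonlinear encoder genuinely
  out-represents a linear projection.
* **Reproductive factors.** Menarche and menopause age are drawn from the
  published category frequencies (uniform within half-integer-aligned
  bins; open-ended bins take the adjacent bin's width), life span is their
  difference exactly, and counts (live births, abortions) take their
  category's integer value.  Standardized menarche age and life span shift
  L with default effects −0.3 each (earlier menarche and shorter
  reproductive life span raise the latent risk, the direction reported in
  the epidemiological literature); L is re-standardized afterwards.
* **Missingness.** Applied only to reproductive factors by default
  (rate 0.05), MCAR or logistic-in-age MAR, through a seed stream separate
  from the cohort draw so re-injection never perturbs the values.

The latent record (L plus pre-missingness factors) is stored for recovery
testing only and is never an input to any inference stage.

What the generator does **not** emulate: skewed or heavy-tailed marginals
(TG with mean 1.73 and SD 1.16 is strongly right-skewed in reality; the
Gaussian emulation admits occasional non-physical negative values),
age-dependence of the biomarkers, multi-factor correlation structure, and
measurement error in self-reported reproductive history.  Consequently a
passing suite shows the pipeline's machinery is correct under the stated
one-factor model, not that real cohorts satisfy that model.

## Condition labels

Labels are screening binaries from inclusive clinical cutoffs, OR-ed
within a condition: pathoglycemia FPG ≥ 6.1 or OGTT-2h ≥ 7.8 mmol/L,
hypertension SBP ≥ 140 or DBP ≥ 90 mmHg, dyslipidemia TC ≥ 6.2, TG ≥ 2.3,
LDL-C ≥ 4.1 or HDL-C < 1.0 mmol/L.  These defaults are declared
assumptions (WHO glucose categories, 140/90 blood pressure, the Chinese
adult dyslipidemia guideline); every threshold is configurable and any
criterion can be deactivated.  A quantile mode places each threshold at a
marginal quantile of the cohort, which is the natural choice for synthetic
units.  A label is 1 if any present criterion fires, 0 if all contributing
markers are present and none fires, and undefined otherwise — so a missing
marker can never veto a positive finding.

## Autoencoder and PCA baseline

Inputs are min-max scaled per feature into [0.1, 0.9] (fit on training
rows only; held-out values extrapolate rather than clip, preserving their
ordering).  The margin keeps targets away from the sigmoid's asymptotes,
where gradients vanish.  Reconstruction MSE is measured in scaled space so
all ten biomarkers contribute comparably regardless of units.

The network is symmetric with a one-unit bottleneck (default
10-8-4-1-4-8-10, 267 parameters — well under the ~1,500 training rows of a
10-fold split of a 1,656-subject cohort, the degrees-of-freedom guard
enforced in hyper-parameter search).  Weights are Glorot-uniform, seeded.
The default optimizer is Adam (learning rate 0.01, batch 32): with targets
compressed into a 0.8-wide interval the per-entry error signal is of order
10⁻², and plain momentum SGD stalls at the mean-predictor plateau for any
practical epoch budget, while Adam's per-parameter step normalisation
escapes it within tens of epochs.  SGD with momentum 0.9 remains available
and is used in tests that need strict full-batch descent.  Early stopping
monitors a 10% validation split with patience 20; the best-epoch weights
are restored and the loss history truncated there, so the final history
entry always equals the delivered model's training MSE.  Analytic
gradients agree with central finite differences to < 10⁻⁵ relative error,
and with identity activations the bottleneck provably recovers the first
principal direction (checked to < 5° against an SVD oracle).

The PCA baseline centres the **raw** biomarkers on training means and
projects onto the first component — the `prcomp` default and the form the
original analysis used.  Min-max scaling is a sigmoid-specific
requirement, not part of the linear baseline.  This choice has a visible
consequence: raw-unit PC1 is dominated by the mmHg-scale blood-pressure
markers (SD 13.75/11.76 vs ≤ 2.1 for the rest), so the PCA score nearly
coincides with the hypertension criterion variables and self-separates
that one condition (AUC ≈ 0.95) while discriminating the glucose and lipid
conditions poorly — which is exactly the qualitative pattern that
motivates the nonlinear score.  A variance-standardized PCA variant was
examined during design; it trades that artifact for a related one (its PC1
pools the four lipid markers' own noise and edges out the autoencoder on
dyslipidemia by ~0.02), because under a monotone one-factor model with
additive independent noise any balanced linear combination retains some
alignment with the labeling markers' noise that a latent-faithful
compression discards.  Under this generative family no one-dimensional
score wins all three conditions simultaneously; the raw-unit baseline was
kept as the specified and historically faithful comparator.

Greedy hyper-parameter search is coordinate-wise — depth, then first
hidden width (later widths halve toward the bottleneck), then learning
rate, then batch size — each axis scored by MSE on a held-out validation
split with identical seeding, with a search log emitted.  Coordinate
descent is not exhaustive; it matches the informal "greedy search"
procedure practitioners describe and is deterministic given the seed.

Model serialization is a JSON manifest (widths, weights, biases, scaler);
Python's shortest-round-trip float representation makes a reloaded model
reproduce encode outputs exactly.

## Evaluation

`cv_auc` fits scaler and reducer on the training folds only and scores the
held-out fold; per-fold scaler extrema are logged so leakage is auditable.
Fold scores are sign-oriented against held-out fasting plasma glucose
(higher GCC = worse) before AUC; orientation is recorded and idempotent.
The 95% CI for a mean fold AUC uses the t distribution with K−1 degrees of
freedom on the fold spread — consistent with "AUC based on 10-fold
cross-validation" — rather than a DeLong-type analytic variance.  Methods
are compared by a **paired** two-tailed t-test on the shared folds (the
folds are common to both methods, so pairing is the coherent choice); a
zero-variance nonzero difference reports p = 0.  Leave-one-out (K = n) is
rejected outright because single-row folds have undefined AUC.  Final ROC
curves come from a refit on all rows, with the optimal threshold by
Youden's J (ties broken toward higher specificity, then higher threshold).

## Association stage

Age is force-entered (the analysis is age-adjusted by design); the five
reproductive factors compete by forward stepwise entry on the partial-F
p-value at α = 0.05.  Candidates whose addition makes the design
rank-deficient or ill-conditioned (condition number > 10¹⁰) are skipped
and logged.

Chained-equation imputation uses scikit-learn's IterativeImputer with
Bayesian-ridge conditionals and posterior sampling — i.e. each of the m
chains redraws missing cells from a fitted conditional with noise — run
with an offset seed per imputation.  Count variables are imputed on the
continuous scale.  Reproductive life span is **never** imputed directly:
cells determined by the other two trio members are completed
deterministically first, chained equations impute menarche and menopause,
and life span is re-derived as their difference in every completed
dataset.  Imputing the trio independently breaks the defining identity on
imputed rows, and a stepwise fit will then exploit pure imputation noise
in the near-collinear trio, producing meaningless coefficients of
arbitrary magnitude.  The cost of the passive scheme is that on rows where
both parents were missing, an observed life span value is superseded by
the derived one (~3% of rows at 20% missingness per factor).

Stepwise selection is re-run within each completed dataset; pooling covers
the union of entered variables with m reduced for partial entrants.
Rubin's rules are implemented directly (Q̄, W, B, T = W + (1+1/m)B, the
classic df formula), with the all-identical-estimates case short-circuited
so that the no-missing pipeline equals a single OLS fit bit-for-bit.
Coefficients are reported as exp(Q̄) with exponentiated CI bounds emitted
sorted as (low, high); the output explicitly flags these as exponentiated
linear-regression coefficients, not odds ratios from a logistic model.

A structural property of this design worth knowing: because life span
equals menopause minus menarche exactly, menopause age is the sum of the
two planted causes and always carries the strongest marginal association
with the latent factor, so forward stepwise enters it first; given
menopause, menarche and life span are exactly collinear, at most one of
them can follow, and life span's partial coefficient given menopause has
the opposite sign to its marginal effect.  The planted negative effects
are therefore recovered as *total* effects (β_menarche + β_menopause and
β_lifespan + β_menopause, both negative), not necessarily as the raw
per-variable coefficients — the property the test suite asserts.  Real
self-reported data, where the identity holds only approximately, can print
all three coefficients simultaneously.

## Pipeline

`run_all` executes cohort → descriptives → labels → reduction → evaluation
→ association → report, writing each stage's outputs (plain CSV/JSON)
before the next begins.  All stage seeds derive from one config seed; two
runs from the same config are byte-identical (the manifest's config hash
covers the semantically meaningful fields — not the output directory or
report formats).  GCC is computed on complete-biomarker rows only;
biomarker missingness is not imputed at the reduction stage.

## Problem sizes

Defaults were chosen to mirror the study scale: cohorts of n = 1,656
(configurable; recovery and comparison studies use n = 2,000), 10-fold
cross-validation, m = 5 imputations, three seeds for seed-averaged
comparisons and ten seeds for the sign-recovery study.

## Known limitations

* One latent factor is the minimal structure under which a single
  compressed score is well defined; real metabolic data are plausibly
  multi-factorial.
* Gaussian marginals misrepresent skewed analytes (TG above all).
* Condition labels derive from the same biomarkers being compressed, so a
  score correlated with a marker's noise can look "better" for that
  marker's condition — the mechanism behind both PCA artifacts described
  above.
* Exponentiated linear coefficients are an interpretability convention,
  not odds ratios.
* HbA1c and uric acid, relevant to these conditions, are outside the
  biomarker panel.
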