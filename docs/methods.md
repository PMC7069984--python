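# Methods

## Problem setting

`tinndep` implements a tabular clinical-prediction pipeline for chronic
tinnitus outpatients: predict whether a patient's depression is *clinical*
(ADSL sum ≥ 16) or *subclinical* (≤ 15) at the end of a multimodal
7-day treatment (T1), using only information available before treatment
(T0): 185 features from seven questionnaires (ADSL, PSQ, SF8, TQ, TLQ,
TINSKAL, SOZK) plus socio-demographics.  The methodological core is an
incremental feature-selection wrapper built on *model reliance*, a
permutation-based importance statistic.  Because clinical cohorts of this
kind are not freely redistributable, the package includes a synthetic
cohort generator calibrated so that the simulated population reproduces
the descriptive statistics such a cohort exhibits.

## Synthetic cohort model

### Depression scores

Each patient carries latent Gaussian depression traits `z0, z1` for the
two time points.  The observable sum scores are produced by a copula
construction with three solved ingredients:

1. **Marginals.**  The T0 and T1 sum-score marginals are Weibull
   distributions, discretised by rounding and clipped to `[0, 60]`.  For
   each time point the two Weibull parameters are solved from the target
   mean and target clinical prevalence (`P(X ≥ 15.5)`).  The Weibull family
   is used because a Gamma with the T1 target mean cannot reach the T1
   tail mass at the cutoff, while the Weibull solution exists and its
   implied SDs (≈11.6 at T0, ≈10.3 at T1) land close to the descriptive
   values (11.7 / 10.7) without being fitted to them.

2. **Sex effect.**  Sex shifts the latent additively (`+δ_F` for women,
   `−δ_M` for men, population-weighted to mean zero).  The shifts have a
   closed-form solution from the female/male prevalence targets.  Each
   shifted latent is mapped through its *exact* mixture CDF, so the
   overall score marginal is unaffected by the shift while the within-sex
   prevalences split as configured.

3. **Dependence.**  The copula correlation ρ between `z0` and `z1` is
   solved (Brent + bivariate-normal orthant evaluations) so that the
   *both-clinical* probability matches the configured transition table.
   Together with the marginals this pins all four transition cells.

A Gaussian copula that reproduces the transition table implies a T0/T1
Spearman correlation of ≈ 0.77, above the 0.71 target: in such cohorts,
concordance at the clinical threshold is stronger than global rank
concordance, an asymmetry no single elliptical copula can express.  The
generator therefore re-assigns the T1 latent of a fraction π of patients
by random permutation *within* T1 outcome strata.  This models
treatment-response rank instability that leaves class membership intact:
it preserves the T1 marginal and all transition cells exactly while
lowering the rank correlation continuously.  Because Spearman's ρ equals
`12·E[F0(z0)F1(z1)] − 3` and each patient is shuffled independently with
probability π, the statistic is linear in π; both endpoint values are
computed by Gauss–Hermite quadrature (100 nodes) and π is solved exactly.
An infeasible Spearman target (outside the attainable interval) is
rejected with a diagnostic.

All calibration happens at generation time from the configured targets;
no Monte-Carlo fitting is involved, so generation is deterministic given
the seed and runs in ≈ 0.1 s for n = 1,490.

### Other instruments

Tinnitus distress, perceived stress and general health are Gaussian
traits coupled to the *post-shuffle standardized* T1 depression trait with
coefficients `2·sin(π·ρ_S/6)` derived from the configured Spearman targets
(0.53, 0.53, −0.48), plus a small residual correlation structure among
themselves.  Instrument totals follow rounded, range-clipped normal
marginals (TQ: 38.6 ± 17.2 on 0–84, giving ≈ 33% decompensated at the
cutoff of 46; PSQ raw: 75 ± 18 on 30–120, i.e. 0.5 ± 0.2 after the
conventional 0–1 rescaling; SF8 item sum: 24 ± 7.9, so the linear
general-health transform is 41.6 ± 7.1).

**Item generation.**  Score-bearing totals are distributed over their
items with a capacity-constrained urn draw
(`Generator.multivariate_hypergeometric`): exchangeable across items and
*exactly* consistent — every stored scale score is recomputable from its
items, which the test suite asserts.  Items that carry no calibrated
total (TLQ quality items, the ten unscored TQ items, TINSKAL
visual-analogue scales) are produced graded-response style: a noisy copy
of the instrument trait, thresholded at equal-mass normal quantiles, with
the trait weight set by `latent_loadings`.  Age is `N(49.8, 12.2²)`
truncated at 18 and independent of outcome (matching the ≈ 0 reported
correlation); categorical socio-demographics follow configurable priors.

### What the generator does and does not emulate

The generator reproduces marginal score distributions, the clinical
transition table, sex contrast and cross-instrument rank correlations.
It does **not** model real psychometric item content (no item wording, no
differential item functioning, no reverse-worded response styles),
item-level factor structure beyond a single trait per instrument, or
informative missingness (missingness injection is MCAR by design, since
the downstream analysis is complete-case only).  Consequently, passing
calibration tests shows the pipeline behaves correctly under the
documented population structure — not that classifier AUCs on real
patients would match: headline AUCs from clinical data are not
reproduction targets here.

A second generator, `make_planted_classification`, produces a logistic
outcome with `n_signal` planted standard-normal predictors (coefficient
0.9 each by default, Bayes AUC ≈ 0.87 at five planted features) plus pure
noise columns, and is the ground truth for wrapper-recovery experiments.

## Feature assembly

The default battery yields exactly 185 columns: 128 single items, 23
sub-scale/total scores, 31 one-hot indicators and 3 numeric covariates.
One-hot encoding keeps the full indicator set (no reference level):
penalised models tolerate the collinearity and per-level indicators are
the interpretable unit.  Ordinal items enter as numeric, unstandardised;
standardisation is owned by the CV pipeline so scaler statistics are fit
inside training folds only.  Exclusion is listwise over all instruments
at both time points; there is no imputation path.  Every feature carries
provenance (`instrument`, `kind`, `source`, `timepoint`), and assembly
rejects any feature not derived purely from T0 — the outcome is the only
T1-derived quantity.

Cutoffs are inclusive exactly as documented (depression: ≤ 15 vs ≥ 16;
tinnitus distress: ≤ 46 vs ≥ 47); scores are integers, so the boundaries
are unambiguous.

## Cross-validation and tuning

Classifiers are tuned by exhaustive grid search under stratified 10-fold
cross-validation, scoring each grid point by mean out-of-fold AUC on one
shared fold assignment per (seed, iteration).  Tuning and reporting share
the same folds (no outer loop), matching the wrapper's per-iteration
"best configuration" semantics; this is an optimistic scheme and is the
documented default rather than a hidden choice.  Grids list values from
most regularised to least; exact AUC ties keep the earlier (simpler)
point.  Default grids: 10 log-spaced penalties in `[1e-3, 1e2]` for
lasso/ridge; neighbour counts {50, 20, 10, 5} for distance-weighted k-NN;
small depth/leaf grids for the tree ensembles.  Methods without native
probabilities (SVM) supply a monotone margin transform; AUC is rank-based
so the link is immaterial.

## Model reliance

For a fitted model ζ, data X, outcome y and loss L, the reliance on
feature f is

    MR(f, ζ) = E_perm[ L(y, ζ(X with f permuted)) ] / L(y, ζ(X)),

estimated by averaging over 10 independent uniform permutations by
default.  The identity permutation is not excluded (the estimate stays
unbiased for the permutation expectation).  The default loss is
`1 − AUC`, aligning the reliance loss with the tuning metric; log-loss
(scores clipped at 1e-15) and misclassification at 0.5 are selectable.
Degenerate cases are explicit: if the original error is 0, MR is 1 when
permuted error is also 0, else +∞ with a flag (and +∞ sorts above any
finite value during selection).  A permutation that leaves the score
vector unchanged yields MR = 1 *exactly* (guarded against summation
round-off), so a feature with a zero coefficient can never survive a
strict cutoff of 1.  By default MR is computed on the training data with
the model refit on the full dataset at the tuned hyperparameters; an
out-of-fold variant (`mr_on="oof"`) scores permutations through the
per-fold models instead.

## Incremental feature selection

Iteration i tunes on the current feature set F_i, refits at the winning
hyperparameters, computes the reliance table, and retains
`{f : MR(f) > cutoff}` with a strict inequality and cutoff 1 by default
(exposed as a tuning knob).  Termination: (a) no feature exceeds the
cutoff — an empty retained set is folded into this reason, with the
current iteration's model as final; (b) the retained set equals the
current set (fixed point).  Since retained sets otherwise shrink
strictly, the loop halts in at most |F|+1 iterations; a per-iteration
classifier failure truncates the trace with the failure recorded as the
termination reason.  Dropped features never return (greedy by design; no
backtracking variant is provided).  `best_iteration` selects either the
AUC argmax (ties → fewer features) or, under `parsimony(δ)`, the smallest
feature set within δ of the best AUC — the trade-off rule that prefers,
e.g., a 6-feature model at 0.850 over a 185-feature model at 0.867 when
δ = 0.02.

## Reporting

Threshold metrics use the ≥ rule at the threshold (a score of exactly 0.5
counts positive — documented because conventions differ) and report
zero-denominator ratios as NaN, never 0.  Coefficient stability across
folds uses the median and the *unscaled* median absolute deviation (no
1.4826 factor — descriptive use) plus the count of folds with a nonzero
coefficient.  Baseline tables compare two groups (default: tinnitus
status at the TQ cutoff) with the unpaired two-tailed t-test,
Mann–Whitney test or chi-square test without continuity correction, raw
p-values, no multiplicity correction.  The performance grid is the
classifier-by-iteration matrix of mean CV AUC with feature counts,
em-dash cells after termination and the per-classifier best flagged.

## Numerical choices and problem sizes

* All randomness flows from one root seed through CRC-32-named child
  streams (`SeedSequence([seed, crc32(label), ...])`), so adding a stream
  never perturbs existing ones and every pipeline stage is reproducible
  bit-for-bit.
* Weibull/shift/copula solves use Brent's method (xtol 1e-10); the
  shuffle fraction uses 100-node Gauss–Hermite quadrature.
* Calibration checks run 10 cohorts of n = 1,490 and test each statistic
  within ±3 SE of the across-seed mean; wrapper-recovery experiments use
  n = 1,000 with 5 planted + 45 noise features over 10 seeds — sizes
  chosen so the full suite completes in well under a minute on one CPU
  while keeping Monte-Carlo error far below the tested tolerances.
* The exhaustive model-reliance oracle enumerates all 720 permutations at
  n = 6; the AUC implementation is checked against a brute-force pairwise
  oracle to 1e-12 on 1,000 random instances.

## Known limitations

* The SD of the within-patient change score is an emergent property of
  the copula (≈ 7.5 under defaults) and is not independently
  controllable; `treatment_effect_sd` is descriptive metadata.
* The within-stratum shuffle is a pragmatic dependence device: it
  reproduces the printed joint statistics but is not a mechanistic model
  of treatment response.
* The 185-column battery allocation (items per sub-scale, categorical
  levels) is a documented default, overridable via the schema; it honours
  the instruments' score ranges, not their verbatim item inventories.
* Tuning and evaluation share folds; reported CV AUCs are therefore
  slightly optimistic, as in the wrapper scheme it mirrors.  A nested
  evaluation is out of scope.
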