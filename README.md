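# tinndep

Predicting post-treatment depression status in chronic tinnitus patients
from pre-treatment questionnaire data — as a tested, reusable pipeline.

Tinnitus and depression are tightly comorbid: knowing *before* a
multimodal outpatient treatment which patients will still report clinical
depression *after* it would help select therapeutic strategies and design
leaner questionnaires.  `tinndep` implements that prediction problem
end-to-end for a battery of seven instruments (ADSL depression scale, PSQ
perceived stress, SF8 general health, TQ tinnitus questionnaire, TLQ,
TINSKAL visual-analogue scales, SOZK socio-demographics):

* a **synthetic cohort generator** that simulates n ≈ 1,490 patients with
  the marginal scores, clinical transition table, sex contrast and
  cross-instrument correlations such cohorts exhibit, so the whole
  pipeline is testable without clinical data;
* a **feature builder** producing the 185-column design matrix (single
  items as numerics, sub-scale/total scores, full one-hot indicator sets)
  and the binary outcome: ADSL sum at end of treatment dichotomised at
  the clinical cutoff of 16;
* **stratified 10-fold cross-validation with AUC-driven grid search**
  over a registry of classifiers (lasso, ridge, k-NN, naive Bayes, CART,
  random forest, gradient boosting, optionally SVM and a small MLP);
* **model reliance**: the permutation importance ratio

      MR(f, ζ) = E[ L(y, ζ(X_perm f)) ] / L(y, ζ(X)),

  averaged over 10 permutations, with `1 − AUC` as the default loss;
* an **incremental feature-selection wrapper** that repeats
  *tune → refit → score reliance → retain MR > 1* until no feature
  qualifies or the set reaches a fixed point, recording a full per-
  iteration trace;
* **reporting**: threshold metrics (accuracy, sensitivity, specificity,
  precision, NPV), coefficient median ± MAD stability across folds,
  baseline-characteristics tables, and classifier-by-iteration AUC grids.

See `docs/methods.md` for the generative model, the calibration solvers
and all numerical conventions.

## Worked example

```python
from tinndep import (GeneratorConfig, generate_cohort, assemble_features,
                     ClassifierSpec, IFSConfig, run_ifs, best_iteration,
                     metrics_at_threshold)

cohort = generate_cohort(GeneratorConfig(n_patients=1490, seed=42))
fm = assemble_features(cohort)
print(f"cohort: n={cohort.n}, features: {fm.n_features}, "
      f"clinical at T1: {fm.y.mean():.1%}")

spec = ClassifierSpec("lasso", grid={"C": (0.01, 0.1, 1.0)})
trace = run_ifs(fm.X, fm.y.to_numpy(), spec,
                IFSConfig(k=10, n_repeats=10, seed=0))
for rec in trace.records:
    print(f"iteration {rec.index}: AUC {rec.mean_auc:.3f} ± {rec.sd_auc:.3f} "
          f"({rec.n_features} features)")
print("termination:", trace.final.termination)

best = best_iteration(trace, "parsimony", delta=0.02)
rec = trace.records[best - 1]
m = metrics_at_threshold(fm.y.to_numpy(), rec.cv.oof_scores, 0.5)
print(f"selected iteration {best}: {rec.n_features} features")
print(f"accuracy {m.accuracy:.2f}, sensitivity {m.sensitivity:.2f}, "
      f"specificity {m.specificity:.2f}")
```

prints (exactly, for this seed):

```
cohort: n=1490, features: 185, clinical at T1: 33.0%
iteration 1: AUC 0.903 ± 0.026 (185 features)
iteration 2: AUC 0.912 ± 0.015 (70 features)
iteration 3: AUC 0.912 ± 0.017 (69 features)
termination: fixed_point
selected iteration 3: 69 features
accuracy 0.84, sensitivity 0.73, specificity 0.90
```

Reading: the wrapper drops 115 of 185 features in one pass without losing
cross-validated AUC (here it even gains a little — permuting uninformative
features adds pure noise to the model), then stabilises at a fixed point
of 69 features.  The parsimony rule picks the smallest feature set within
0.02 AUC of the best iteration; the confusion metrics come from
out-of-fold scores dichotomised at a probability of 0.5.  Absolute AUC
levels on synthetic cohorts reflect the generator's latent structure, not
clinical reality.

The same pipeline is scriptable from the shell:

```sh
tinndep simulate --seed 42 --out cohort.csv
tinndep build-features --in cohort.csv --out features.csv
tinndep run-ifs --features features.csv --classifier lasso --out results/
tinndep evaluate --features features.csv --classifier lasso --out results/
tinndep report --cohort cohort.csv --out results/
```

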