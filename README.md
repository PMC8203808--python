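# neurophantom

MRI-based Alzheimer's-disease classification, rebuilt as a fully testable
pipeline on synthetic brain phantoms.

Studies that classify AD patients against controls from structural MRI — and
then ask whether the trained classifier survives contact with an external
cohort or with conversion prediction in mild cognitive impairment (MCI) —
are normally tied to access-restricted cohorts. This package implements the
whole analysis as a reusable library and substitutes the data with a
synthetic phantom generator that implants the statistical structure the
analysis assumes, so every claim the pipeline makes is verifiable on a
laptop.

It provides:

* **Phantom cohorts** — internal ("research-cohort-like") and external
  ("memory-clinic-like") populations of 3D NIfTI volumes with group-wise
  regional atrophy `I(v) = icv·T(v)·(1 − δ_g·R(v))·gain_site + noise`,
  head-size variation, site intensity shift, and two representations per
  subject: aligned modulated-GM-density maps and minimally aligned
  T1w-like images with residual misalignment and bias fields.
* **Voxel-feature linear SVM** with inner-CV choice of C and analytic
  permutation significance maps (p-maps): the least-norm all-support-vector
  weight map is linear in the labels, `w = M y`, so permutation mean and
  variance per voxel are closed-form and p ≤ 0.05 clusters
  (26-connectivity, uncorrected) come without running permutations.
* **3D all-convolutional network** — seven blocks of stride-1 + stride-2
  3³ convolutions with dropout, batch norm and ReLU (filters
  16-32-32-64-64-32-16), trained with within-class mixup (0.8/0.2, 1000
  samples/class), Adam with step decay, and early stopping on validation
  AUC; guided-backpropagation saliency maps averaged over correctly
  classified patients. The engine is pure numpy with hand-derived
  backward passes — no deep-learning framework required.
* **Evaluation statistics** — AUC/accuracy over 20 shared stratified 90/10
  splits, corrected resampled t-test confidence intervals
  (`mean ± t·sqrt((1/k + n_test/n_train)·s²)`), 500-sample bootstrap CIs on
  held-out test sets, McNemar chi-square comparisons with Bonferroni
  control (α/4).
* **An experiment runner** covering internal cross-validation, retraining
  on the full internal AD+CN population, transfer to internal MCI and to
  the external cohort, and map rendering with Dice overlap against the
  generator's ground-truth ROI.

## Worked example

```python
from neurophantom.phantoms import PhantomConfig
from neurophantom.runner import ExperimentConfig, ExperimentRunner

config = ExperimentConfig(
    phantom=PhantomConfig(
        shape=(32, 32, 32),
        n_internal={"AD": 30, "CN": 30, "MCIc": 10, "MCInc": 10},
        n_external={"AD": 10, "SCD": 10, "MCIc": 5, "MCInc": 6},
        seed=42,
    ),
    classifiers=("svm",),
    k_splits=10,
    out_dir="scratch/demo",
    seed=42,
)
runner = ExperimentRunner(config)
runner.ensure_cohort()

cv = runner.run_internal_cv()
for (clf, rep), res in ((k, v) for k, v in cv.items() if isinstance(k, tuple)):
    print(f"{clf:4s} {rep:13s} AUC {res.mean_auc:.3f} "
          f"(95% CI {res.ci_auc[0]:.3f}-{res.ci_auc[1]:.3f})")

transfer = runner.run_transfer()
for task in ("internal_mci", "external_ad_scd", "external_mci"):
    res = transfer[(task, "svm", "modulated_gm")]
    print(f"{task:16s} AUC {res.mean_auc:.3f} "
          f"(bootstrap CI {res.ci_auc[0]:.3f}-{res.ci_auc[1]:.3f})")

maps = runner.render_maps(transfer["fitted"], transfer["train_ids"])
print("p-map cluster Dice vs implanted ROI:",
      round(maps[("svm", "modulated_gm")]["dice_roi"], 3))
```

prints

```
svm  modulated_gm  AUC 1.000 (95% CI 1.000-1.000)
svm  minimal_t1w   AUC 1.000 (95% CI 1.000-1.000)
internal_mci     AUC 0.960 (bootstrap CI 0.844-1.000)
external_ad_scd  AUC 1.000 (bootstrap CI 1.000-1.000)
external_mci     AUC 1.000 (bootstrap CI 1.000-1.000)
p-map cluster Dice vs implanted ROI: 0.907
```

At the default effect sizes the internal diagnostic task is cleanly
separable, conversion prediction (MCIc vs MCInc, trained on AD vs CN) is
harder — the intended gradient — and the largest significant p-map cluster
recovers the implanted atrophy region (Dice 0.91). The same `runner` drives
the CNN cells (`classifiers=("svm", "cnn")`); a CLI mirrors the library
(`neurophantom simulate|run-cv|run-transfer|render-maps|report`, each with
`--config/--out/--seed`).

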