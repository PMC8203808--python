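# Methods

## Problem and scope

The package implements an MRI-based dementia-classification pipeline — the
kind used to separate Alzheimer's disease (AD) patients from controls (CN)
on structural T1-weighted scans and to probe how such classifiers
generalize to an external cohort and to conversion prediction in mild
cognitive impairment (MCI). Because the real cohorts such studies use
(research databases and clinical biobanks) are access-restricted, the
package ships a synthetic brain-phantom generator with the statistical
structure the analysis assumes, so every stage — preprocessing, both
classifier families, significance/saliency maps, and the evaluation
statistics — is exercised and tested end to end without any download.

Two input representations are modeled:

* **modulated-GM-like maps** — spatially aligned, smooth, non-negative
  gray-matter density images whose intensities scale with local GM volume
  and with head size (intracranial volume, ICV);
* **minimal-T1w-like images** — a three-tissue contrast rendering aligned
  only up to a similarity transform, so residual nonrigid anatomical
  misalignment and a multiplicative bias field remain.

## Phantom generator

A template GM density field `T(v) ∈ [0,1]` lives inside an ellipsoidal
brain mask, with a spherical "disease ROI" (a medial-temporal surrogate)
strictly inside the brain. Subject maps follow

    I(v) = icv · T(v) · (1 − δ_g · R(v)) · gain_site + site_field(v) + ε(v)

* `δ_g` — fractional GM loss per group; defaults δ_AD = 0.30,
  δ_MCIc = 0.18, δ_MCInc = 0.08, δ_CN = δ_SCD = 0. Converters sit between
  controls and AD, non-converters below converters, so conversion
  prediction is a harder version of the diagnostic task, as observed in
  real cohorts.
* `R` — ROI indicator smoothed with a Gaussian (σ = 1 voxel) and rescaled
  to a unit core. The soft edge avoids aliasing of the effect boundary; it
  also means the implanted core contrast matches `(1−δ_a)/(1−δ_b)` to
  about 1% rather than exactly, and contrast-recovery tests use that
  tolerance.
* `icv` — multiplicative head-size factor, uniform on (0.9, 1.1); the
  participants table records it so preprocessing can divide it out.
* `gain_site`, `site_field` — per-site multiplicative gain and smooth
  additive field; the external cohort's site uses gain 1.1 and field
  amplitude 0.02, injecting the cross-cohort distribution shift.
* `ε` — smooth Gaussian noise rescaled to σ = 0.05 within the brain.

Minimal-T1w images render three intensity plateaus (CSF 0.2 < GM 0.55 <
WM 0.85) by thresholding the subject's GM map, then apply a random
similarity jitter (rotation ≤ 3°, isotropic scale ±3%), a smooth random
deformation (amplitude 1.5 voxels, σ = 4 voxels; a Jacobian positivity
guard rejects folding warps), and a multiplicative bias field
(amplitude 0.1, σ = 8 voxels). Atrophy moves ROI voxels from the GM to
the WM plateau, which is how the group signal survives into this
representation. The residual-misalignment amplitude after similarity-only
alignment is not identifiable from published material; the default is a
plausible guess and is config-exposed.

Everything is a pure function of the configuration seed: records carry
per-subject seeds spawned from the cohort seed, so cohorts regenerate
bit-identically.

What the phantoms deliberately do **not** model: scanner physics and
vendor/protocol differences, real anatomical variability, partial-volume
effects, registration failure modes, age/sex covariates, and any
time-to-event structure behind "conversion" (MCI labels are defined purely
by the generator's effect sizes). Passing tests therefore demonstrate that
the pipeline recovers the structure this generator implants — not clinical
performance on real scans.

Default phantom extent is 48³ at 3 mm spacing; tests and the acceptance
suite generate 20³–32³ cohorts so the full suite runs in minutes on one
CPU.

## Preprocessing

Modulated-GM maps are divided by ICV; minimal-T1w images are z-normalized
within the brain mask (population variance, outside-mask voxels set to 0).
Voxel features are the within-mask values in stable C order, standardized
per feature with mean/sd estimated on the training subjects only (sample
variance); zero-variance features get sd := 1 so they become constant 0
without disturbing the voxel index map. Every scaler records the subject
ids it was fit on, and the runner asserts train/test disjointness, so
test-set leakage is structurally excluded.

## Linear SVM and analytic significance maps

The SVM is a soft-margin linear machine; the regularization parameter C is
chosen by inner 5-fold cross-validation maximizing AUC over the grid
10⁻⁵…10¹ (decade steps, ties toward the smaller C — stronger
regularization), then the model is refit on the full training set.

The p-map approximates a voxelwise permutation test of the weight vector
in closed form. In the n ≪ d regime every training point is treated as a
support vector, so the weights solve the least-norm problem
min ‖w‖² s.t. w·xᵢ + b = yᵢ, whose solution is linear in the labels:
w = M y with M = Xᵀ(K⁺ − K⁺11ᵀK⁺ / 1ᵀK⁺1), K = XXᵀ. Under uniformly
random label permutations each component w_j = Σᵢ M_ji y_i has the exact
simple-random-permutation moments

    E[w_j] = n · m̄_j · ȳ,   Var[w_j] = Σᵢ(M_ji − m̄_j)² · Σ_k(y_k − ȳ)² / (n−1),

and a Gaussian two-sided p-value per voxel. Numerical choices: the Gram
pseudo-inverse uses a cutoff of 1e-10 × the largest singular value; when
the ones-vector lies in the null space of K (column-standardized features
give Xᵀ1 = 0) the offset separates out (b = ȳ) and M reduces to XᵀK⁺;
features with numerically zero permutation variance (constant columns)
keep p = 1. Clusters are 26-connected components of p ≤ α (α = 0.05,
uncorrected), sorted by size. The test suite validates the closed form
against a brute-force oracle that re-solves the KKT system for 10,000
actual label permutations (rank correlation ≥ 0.9, shared top-features).

## 3D all-convolutional network

Architecture: seven blocks of [conv(3³, stride 1) → dropout(0.2) → batch
norm → ReLU → conv(3³, stride 2) → dropout → BN → ReLU] with filter widths
(16, 32, 32, 64, 64, 32, 16) on a single-channel input; strided
convolutions replace pooling. The softmax head is under-determined by the
published description; this package uses a 1³ convolution from the last
feature width to 2 class channels followed by global average pooling
(equivalently, a dense layer on pooled features — identical parameter
count), which keeps the network fully convolutional.

The engine is written directly on numpy with hand-derived backward passes
(the k³-offset formulation keeps convolution forward/backward in
BLAS-friendly tensordot calls) and is verified against numerical
gradients. Training follows the stated recipe: 2-class cross-entropy on
softmax outputs, Adam (lr 0.001, ε 1e-8, no decay), learning rate halved
every 10 epochs, batch size 4 by default, a stratified 10% validation
split taken from the *pre-augmentation* subjects, early stopping when the
validation AUC has not improved for 20 epochs, and restoration of the
best-validation-AUC epoch. One refinement: when several epochs tie for
the highest validation AUC (routine on small validation splits of a
separable task, where AUC saturates at 1.0 within a few epochs), the
epoch with the lower validation cross-entropy is kept; the literal
first-best rule returns an undertrained model whose softmax outputs
cluster on one side of 0.5, which degrades every accuracy-based statistic
downstream.

Mixup augmentation balances and enlarges the training set to a fixed
per-class target (1000 by default): each synthesized sample is
0.8·A + 0.2·B for two distinct same-class images, so labels are never
mixed; originals are included in the target by default (config flag to
exclude). Augmentation uses training subjects only — validation content
never leaks into mixed samples. CNN inputs are scaled by the global
mean/sd of the augmented training set.

### Parameter accounting

The builder counts parameters in closed form (each conv 27·c_in·c_out
+ c_out if biased; each BN 2c trainable + 2c running statistics; head
c_last·2 + 2) and cross-checks against direct enumeration of a built
model's weight arrays. The published total for this architecture,
577,498, cannot be reproduced under any defensible convention: the
convolution weights alone sum to 27 × 22,032 = 594,864 for the stated
filter ladder, which already exceeds that figure before biases,
normalization or head parameters are added. The accounting operation
therefore enumerates all candidate conventions (bias on/off × BN
trainable-only/with running statistics × head variants) and reports the
canonical total 597,458 (trainable 596,434); the corresponding acceptance
check documents the discrepancy rather than adopting an ad-hoc
architecture that happens to match the printed number.

### Saliency

Guided backpropagation: the gradient of the linear (pre-softmax)
target-class score with respect to the input, zeroing backward signal at
each ReLU wherever the forward activation or the backward signal is
negative. Maps are averaged over correctly classified AD subjects and
magnitudes below ⅓ of the maximum are zeroed. A consequence of the guided
rule worth noting: on GM-density maps the implanted effect is *negatively*
signed for the AD score (less GM → more AD evidence), so its backward
contribution is systematically clipped and the averaged map is
de-localized; on minimal-T1w renderings atrophy *brightens* voxels
(GM → WM plateau), the effect is positively signed, and the averaged map
concentrates on the implanted ROI (Dice ≈ 0.5 at desk scale). The
ROI-attribution acceptance check therefore evaluates the minimal-T1w
representation. This asymmetry is consistent with published observations
that guided-backprop saliency on GM maps highlights regions outside the
medial temporal lobe.

## Evaluation statistics

* AUC: Mann–Whitney convention (ties ½); accuracy thresholds at 0.5 on the
  positive-class softmax score and at 0 on the SVM decision value, with no
  threshold tuning.
* Split scheme: k = 20 stratified random 90/10 splits; the identical
  scheme object is consumed by every classifier under comparison, and each
  cell's result records the scheme hash.
* Corrected resampled t-interval for repeated splits:
  mean ± t_{k−1} · sqrt((1/k + n_test/n_train) · s²). The inflation term
  accounts for overlapping training sets; the corrected interval always
  contains the naive 1/k interval.
* Bootstrap CIs on held-out test sets: percentile interval over 500
  resamples of subjects; single-class resamples are redrawn.
* McNemar: continuity-corrected chi-square (|b−c|−1)²/(b+c) on the
  discordant counts, 1 df; an exact-binomial variant is exposed for small
  counts; b + c = 0 returns p = 1 with a warning.
* Bonferroni: family α = 0.05 over the declared 4 comparisons per test set
  (SVM-vs-CNN on each representation; representation-vs-representation for
  each classifier), threshold 0.0125.

## Experiment runner

E1 trains and evaluates each (classifier × representation) cell over the
shared split scheme with corrected resampled CIs. E2–E4 retrain each cell
once on all internal AD+CN and apply the frozen models to internal
MCIc–MCInc, external AD–SCD, and external MCIc–MCInc, with bootstrap CIs
and the McNemar family. Map rendering computes the SVM p-map and cluster
masks and the CNN averaged thresholded saliency from the full-training
models, reporting Dice overlap against the generator's ground-truth ROI.
The CNN path trains on volumes downsampled to a configurable extent
(default 16³) with a reduced-depth network (filters 8-16-16-8), a
reduced augmentation target (150/class) and ≤ 25 epochs — desk-scale
choices that keep the numpy engine tractable on one CPU; the full-size
architecture and the published training constants remain the dataclass
defaults.

## Known limitations

* Phantom separability at the default effect sizes is high (internal AD–CN
  AUC near 1.0 at n = 30–50/group), so ordering checks often compare
  saturated values; the MCI tasks and the null configuration provide the
  informative gradations.
* The numpy engine is single-threaded and makes full-resolution
  (≥ 48³, 7-block, 1000/class) CNN training impractical; conclusions about
  the CNN at desk scale rest on reduced-depth models.
* The analytic p-map's Gaussian permutation approximation is validated
  against the brute-force oracle at n = 20; calibration at much larger n
  (where the all-support-vector assumption weakens) is not characterized.
* Bootstrap and corrected-resampled intervals are reported as computed;
  corrected intervals may extend beyond [0, 1] for near-degenerate
  per-split variances.
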