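"""Evaluation statistics for the cross-validated classifier comparison.

Covers: AUC and accuracy, the repeated stratified 90/10 split scheme shared
by every classifier under comparison, corrected resampled t-test confidence
intervals for repeated random splits (the variance inflation 1/k +
n_test/n_train accounts for overlapping training sets), percentile
bootstrap CIs on held-out test sets, McNemar's chi-square comparison of
paired classifiers, and Bonferroni family control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar


@dataclass
class SplitScheme:
    k: int
    test_fraction: float
    splits: list  # list of (train_ids, test_ids)
    seed: int

    def hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for tr, te in self.splits:
            h.update(("|".join(tr) + "#" + "|".join(te)).encode())
        return h.hexdigest()[:16]


@dataclass
class EvalResult:
    per_split_auc: list
    per_split_acc: list
    mean_auc: float
    mean_acc: float
    ci_auc: tuple
    ci_acc: tuple
    ci_method: str
    n_train: int
    n_test: int
    meta: dict = field(default_factory=dict)


@dataclass
class PairedPredictions:
    """Correctness of two classifiers on the same test subjects."""

    subject_ids: list
    correct_a: np.ndarray
    correct_b: np.ndarray

    def __post_init__(self) -> None:
        self.correct_a = np.asarray(self.correct_a, dtype=bool)
        self.correct_b = np.asarray(self.correct_b, dtype=bool)
        if self.correct_a.shape != self.correct_b.shape:
            raise ValueError("paired prediction arrays differ in length")

    @property
    def b(self) -> int:
        """A right, B wrong."""
        return int(np.sum(self.correct_a & ~self.correct_b))

    @property
    def c(self) -> int:
        """A wrong, B right."""
        return int(np.sum(~self.correct_a & self.correct_b))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 1/2."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    return float(np.mean(predictions == labels))


def make_splits(
    labels_by_id: dict[str, int],
    k: int = 20,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> SplitScheme:
    """k stratified random train/test splits, deterministic given seed.

    The identical scheme object must be consumed by every classifier under
    comparison (same-splits requirement).
    """
    ids = np.array(list(labels_by_id.keys()))
    y = np.array([labels_by_id[i] for i in ids])
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < int(np.ceil(1.0 / test_fraction)):
            raise ValueError(
                f"group {cls!r} has {cnt} members; too few for test_fraction={test_fraction}"
            )
    sss = StratifiedShuffleSplit(
        n_splits=k, test_size=test_fraction, random_state=seed
    )
    splits = [
        (list(ids[tr]), list(ids[te])) for tr, te in sss.split(np.zeros_like(y), y)
    ]
    return SplitScheme(k=k, test_fraction=test_fraction, splits=splits, seed=seed)


def corrected_resampled_ci(
    per_split_values: np.ndarray,
    n_train: int,
    n_test: int,
    conf: float = 0.95,
) -> tuple[float, float]:
    """Nadeau-Bengio corrected resampled t-interval for repeated splits.

    CI = mean +/- t_{k-1,(1+conf)/2} * sqrt((1/k + n_test/n_train) * s^2)
    with s^2 the sample variance of the k per-split values.
    """
    v = np.asarray(per_split_values, dtype=float)
    k = v.size
    if k < 2:
        raise ValueError("need at least 2 per-split values")
    s2 = v.var(ddof=1)
    half = stats.t.ppf((1 + conf) / 2, k - 1) * np.sqrt((1.0 / k + n_test / n_train) * s2)
    m = v.mean()
    return (float(m - half), float(m + half))


def bootstrap_ci(
    test_scores: np.ndarray,
    test_labels: np.ndarray,
    metric,
    n_boot: int = 500,
    conf: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a metric over test-subject resamples.

    Single-class resamples are redrawn; if more than half of the draws are
    degenerate the metric is considered undefined on this test set.
    """
    scores = np.asarray(test_scores)
    labels = np.asarray(test_labels)
    if np.unique(labels).size < 2:
        raise ValueError("bootstrap CI needs both classes in the test set")
    rng = np.random.default_rng(seed)
    n = labels.size
    vals = []
    redraws = 0
    while len(vals) < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.unique(labels[idx]).size < 2:
            redraws += 1
            if redraws > n_boot:
                raise ValueError("metric undefined on most bootstrap resamples")
            continue
        vals.append(metric(scores[idx], labels[idx]))
    lo, hi = np.percentile(vals, [100 * (1 - conf) / 2, 100 * (1 + conf) / 2])
    return (float(lo), float(hi))


def mcnemar_test(paired: PairedPredictions) -> tuple[float, float]:
    """Continuity-corrected McNemar chi-square on discordant counts.

    statistic = (|b - c| - 1)^2 / (b + c), 1 df. By convention b + c = 0
    gives p = 1 (no discordant pairs to compare).
    """
    b, c = paired.b, paired.c
    if b + c == 0:
        import warnings

        warnings.warn("no discordant pairs; McNemar p set to 1", stacklevel=2)
        return (0.0, 1.0)
    table = np.array([[0, b], [c, 0]])
    res = _sm_mcnemar(table, exact=False, correction=True)
    return (float(res.statistic), float(res.pvalue))


def mcnemar_exact(paired: PairedPredictions) -> tuple[float, float]:
    """Exact binomial McNemar variant for small discordant counts."""
    b, c = paired.b, paired.c
    if b + c == 0:
        return (0.0, 1.0)
    res = _sm_mcnemar(np.array([[0, b], [c, 0]]), exact=True)
    return (float(res.statistic), float(res.pvalue))


def bonferroni_alpha(family_alpha: float = 0.05, m: int = 4) -> float:
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return family_alpha / m


def summarize_cv(
    per_split_auc, per_split_acc, n_train: int, n_test: int, conf: float = 0.95
) -> EvalResult:
    """Aggregate per-split metrics with corrected resampled t-intervals."""
    return EvalResult(
        per_split_auc=list(map(float, per_split_auc)),
        per_split_acc=list(map(float, per_split_acc)),
        mean_auc=float(np.mean(per_split_auc)),
        mean_acc=float(np.mean(per_split_acc)),
        ci_auc=corrected_resampled_ci(per_split_auc, n_train, n_test, conf),
        ci_acc=corrected_resampled_ci(per_split_acc, n_train, n_test, conf),
        ci_method="corrected_resampled_t",
        n_train=n_train,
        n_test=n_test,
    )
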