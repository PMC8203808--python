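"""Linear SVM on voxel features and analytic permutation significance maps.

The classifier is a soft-margin linear SVM whose regularization parameter C
is chosen by inner 5-fold cross-validation maximizing AUC (ties broken
toward the smallest C), then refit on the full training set.

The p-map approximates a voxelwise permutation test of the SVM weight
vector in closed form. In the high-dimensional regime (n < d) every
training point is treated as a support vector, so the weight vector solves
the least-norm problem

    min ||w||^2   s.t.   w . x_i + b = y_i  for all i,

whose solution is linear in the labels: w = M y with

    M = X^T J,   J = K^+ - (K^+ 1 1^T K^+) / (1^T K^+ 1),   K = X X^T.

Under uniformly random label permutations each component w_j = sum_i M_ji
y_i has closed-form mean and variance (simple-random-permutation moments),
giving a Gaussian two-sided p-value per voxel without running any actual
permutations. A constant feature has a zero M row (J 1 = 0) and so p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .images import BrainMask
from .preprocess import FeatureMatrix, devectorize

DEFAULT_C_GRID = tuple(10.0**k for k in range(-5, 2))

_PINV_RCOND = 1e-10


@dataclass
class TrainedLinearModel:
    weights: np.ndarray  # (n_features,)
    bias: float
    c_value: float
    dual_info: np.ndarray  # per-training-subject signed dual coefficients
    train_ids: list

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {-1, +1}; the decision value thresholded at 0."""
        return np.where(self.decision_function(X) >= 0, 1, -1)


@dataclass
class PMap:
    p_values: np.ndarray  # per-feature, in [0, 1]
    alpha: float
    clusters: list  # list of (k, 3) voxel-coordinate arrays, size-descending

    def __post_init__(self) -> None:
        if np.any(self.p_values < 0) or np.any(self.p_values > 1):
            raise ValueError("p-values must lie in [0, 1]")


def train_linear_svm(
    X: FeatureMatrix,
    y: np.ndarray,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    seed: int = 0,
    n_folds: int = 5,
) -> TrainedLinearModel:
    """Linear SVM with inner-CV choice of C (mean fold AUC, ties -> small C)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    Xv = X.values

    c_grid = tuple(sorted(c_grid))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(Xv, y))
    mean_auc = []
    for c in c_grid:
        aucs = []
        for tr, te in folds:
            clf = SVC(kernel="linear", C=c)
            clf.fit(Xv[tr], y[tr])
            scores = clf.decision_function(Xv[te])
            aucs.append(_fold_auc(scores, y[te]))
        mean_auc.append(np.mean(aucs))
    best = int(np.argmax(mean_auc))  # argmax takes the first max -> smallest C
    c_star = c_grid[best]

    clf = SVC(kernel="linear", C=c_star)
    clf.fit(Xv, y)
    dual = np.zeros(Xv.shape[0])
    dual[clf.support_] = clf.dual_coef_[0]
    return TrainedLinearModel(
        weights=clf.coef_.ravel().astype(np.float64),
        bias=float(clf.intercept_[0]),
        c_value=float(c_star),
        dual_info=dual,
        train_ids=list(X.subject_order),
    )


def _fold_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    if np.unique(labels).size < 2:
        return 0.5
    return roc_auc_score(labels, scores)


def pmap_linear_map(X: np.ndarray) -> np.ndarray:
    """The matrix M with w = M y for the all-support-vector least-norm SVM."""
    X = np.asarray(X, dtype=np.float64)
    K = X @ X.T
    Kinv = np.linalg.pinv(K, rcond=_PINV_RCOND)
    u = Kinv @ np.ones(K.shape[0])
    s = u.sum()
    # If the ones-vector lies in the null space of K (e.g. column-standardized
    # features give X^T 1 = 0), the offset solves separately (b = mean(y)) and
    # the weight map reduces to w = X^T K^+ y.
    if abs(s) < 1e-10 * np.abs(Kinv).sum():
        return X.T @ Kinv
    J = Kinv - np.outer(u, u) / s
    return X.T @ J


def analytic_pmap(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
) -> PMap:
    """Closed-form permutation p-value per feature for the SVM weight map."""
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, d = Xv.shape
    if n >= d:
        import warnings

        warnings.warn(
            "analytic p-map assumes the high-dimensional regime n < d; "
            f"got n={n}, d={d}", stacklevel=2,
        )
    M = pmap_linear_map(Xv)  # (d, n)
    w = M @ y

    ybar = y.mean()
    sy2 = np.sum((y - ybar) ** 2)
    mbar = M.mean(axis=1)
    mu = n * mbar * ybar
    var = np.sum((M - mbar[:, None]) ** 2, axis=1) * sy2 / (n - 1)

    p = np.ones(d)
    # features with (numerically) zero permutation variance are constant under
    # every labeling (J 1 = 0 kills constant columns) and keep p = 1
    pos = var > 1e-12 * max(var.max(), 1e-300)
    z = np.abs(w[pos] - mu[pos]) / np.sqrt(var[pos])
    p[pos] = 2.0 * stats.norm.sf(z)
    return PMap(p_values=np.clip(p, 0.0, 1.0), alpha=alpha, clusters=[])


def threshold_pmap(pmap: PMap, mask: BrainMask, alpha: float | None = None) -> PMap:
    """Clusters (26-connectivity) of voxels with p <= alpha, size-descending."""
    alpha = pmap.alpha if alpha is None else alpha
    p_vol = np.ones(mask.shape)
    p_vol[mask.data] = pmap.p_values
    sig = (p_vol <= alpha) & mask.data
    labels, n = ndimage.label(sig, structure=np.ones((3, 3, 3), dtype=int))
    clusters = [np.argwhere(labels == k) for k in range(1, n + 1)]
    clusters.sort(key=len, reverse=True)
    return PMap(p_values=pmap.p_values, alpha=alpha, clusters=clusters)


def cluster_mask(pmap: PMap, mask: BrainMask, largest_only: bool = False) -> np.ndarray:
    """Boolean volume of (the largest of) the significant clusters."""
    out = np.zeros(mask.shape, dtype=bool)
    use = pmap.clusters[:1] if largest_only else pmap.clusters
    for c in use:
        out[tuple(c.T)] = True
    return out


def weight_volume(model: TrainedLinearModel, mask: BrainMask):
    """Render the SVM weight vector into brain space."""
    return devectorize(model.weights, mask)
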