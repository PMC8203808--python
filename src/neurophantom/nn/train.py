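"""Training loop: Adam, step-decay schedule, early stopping on validation AUC.

The stated procedure: 2-class cross-entropy on softmax outputs, Adam
(lr 0.001, eps 1e-8, weight decay 0), learning rate halved every 10 epochs,
batch size 4, training stopped once validation AUC has not improved for 20
epochs, and the weights of the best-validation-AUC epoch returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .layers import cross_entropy_grad
from .network import AllConvNet


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    adam_eps: float = 1e-8
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    lr_halving_epochs: int = 10
    batch_size: int = 4
    val_fraction: float = 0.10
    early_stop_patience: int = 20
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        for name in ("learning_rate", "adam_eps", "batch_size",
                     "early_stop_patience", "max_epochs", "lr_halving_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Step decay: lr0 / 2^floor((epoch - 1) / halving_epochs), epochs 1-based."""
    return cfg.learning_rate / 2 ** ((epoch - 1) // cfg.lr_halving_epochs)


def select_best_epoch(val_aucs: list[float], patience: int) -> tuple[int, int]:
    """(best_epoch, stop_epoch), both 1-based, for a validation-AUC history.

    Training halts after the first epoch at which the best AUC is `patience`
    epochs old; the model of the best epoch is kept. Pure function so the
    early-stopping semantics are testable on scripted histories.
    """
    best, best_epoch = -np.inf, 0
    for e, v in enumerate(val_aucs, start=1):
        if v > best:
            best, best_epoch = v, e
        if e - best_epoch >= patience:
            return best_epoch, e
    return best_epoch, len(val_aucs)


class Adam:
    def __init__(self, params: list, cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]
        self.t = 0

    def step(self, lr: float) -> None:
        cfg = self.cfg
        self.t += 1
        b1, b2 = cfg.adam_beta1, cfg.adam_beta2
        for i, (_, val, grad) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad * grad
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            val -= lr * mhat / (np.sqrt(vhat) + cfg.adam_eps)


def _onehot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((labels.size, n_classes), dtype=np.float32)
    out[np.arange(labels.size), labels.astype(int)] = 1.0
    return out


def train_cnn(
    model: AllConvNet,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig,
) -> dict:
    """Fit in place; returns history {epoch, lr, train_loss, val_auc}.

    Expects the training set to be already augmented and scaled, and the
    validation set to come from pre-augmentation subjects (leakage-safe
    split). Labels are class indices {0, 1}; class 1 is the positive
    (patient) class whose softmax score ranks subjects for AUC.
    """
    if val_images.shape[0] == 0:
        raise ValueError("empty validation split")
    if np.unique(val_labels).size < 2:
        raise ValueError("validation split needs both classes for AUC")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg)
    n = train_images.shape[0]
    history: dict = {"epoch": [], "lr": [], "train_loss": [], "val_auc": [],
                     "val_loss": []}
    best_auc, best_epoch, best_weights = -np.inf, 0, model.get_weights()
    best_loss = np.inf
    best_auc_strict, best_auc_epoch = -np.inf, 0

    for epoch in range(1, cfg.max_epochs + 1):
        lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.forward(train_images[idx], training=True)
            loss, dlogits = cross_entropy_grad(logits, _onehot(train_labels[idx]))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; last lr {lr}"
                )
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
        val_proba = model.predict_proba(val_images)
        val_scores = val_proba[:, 1]
        val_auc = roc_auc_score(val_labels, val_scores)
        val_loss = float(-np.mean(np.log(np.clip(
            val_proba[np.arange(val_labels.size), val_labels.astype(int)],
            1e-12, None))))
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_auc"].append(float(val_auc))
        history["val_loss"].append(val_loss)
        # model selection: highest validation AUC; exact ties broken by the
        # lower validation cross-entropy (better-calibrated epoch)
        if val_auc > best_auc or (val_auc == best_auc and val_loss < best_loss):
            best_auc, best_epoch, best_loss = val_auc, epoch, val_loss
            best_weights = model.get_weights()
        # patience clock runs on AUC improvement only
        if val_auc > best_auc_strict:
            best_auc_strict, best_auc_epoch = val_auc, epoch
        if epoch - best_auc_epoch >= cfg.early_stop_patience:
            break

    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_auc"] = float(best_auc)
    return history


def predict(model: AllConvNet, images: np.ndarray) -> np.ndarray:
    """Per-class softmax scores, (N, 2); rows sum to 1."""
    return model.predict_proba(images)
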