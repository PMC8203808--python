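"""Within-class mixup augmentation to a fixed per-class sample count.

Each synthesized image is the fixed convex combination 0.8*A + 0.2*B of two
distinct, randomly chosen images of the *same* class, so labels are never
mixed and class balance is exact by construction. By default the original
images are included among the per-class target and synthesized samples fill
the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AugmentConfig:
    per_class_target: int = 1000
    mix_fraction: float = 0.8  # weight of the first image; second gets 1 - this
    include_originals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mix_fraction < 1.0:
            raise ValueError("mix_fraction must be in (0, 1)")
        if self.per_class_target < 1:
            raise ValueError("per_class_target must be >= 1")


def mixup_augment(
    images: np.ndarray, labels: np.ndarray, cfg: AugmentConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Balance and enlarge a training set to ``per_class_target`` per class.

    ``images``: (N, ...) array; ``labels``: (N,). Returns exactly
    ``per_class_target`` samples for every class present, deterministic
    given ``cfg.seed``.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)
    out_imgs, out_labels = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 images; cannot mix")
        target = cfg.per_class_target
        if cfg.include_originals:
            keep = idx[:target]
            out_imgs.append(images[keep])
            out_labels.append(np.full(keep.size, cls, dtype=labels.dtype))
            n_syn = target - keep.size
        else:
            n_syn = target
        if n_syn > 0:
            a = rng.integers(0, idx.size, size=n_syn)
            shift = rng.integers(1, idx.size, size=n_syn)
            b = (a + shift) % idx.size  # guaranteed distinct from a
            mixed = (cfg.mix_fraction * images[idx[a]]
                     + (1.0 - cfg.mix_fraction) * images[idx[b]])
            out_imgs.append(mixed.astype(images.dtype))
            out_labels.append(np.full(n_syn, cls, dtype=labels.dtype))
    return np.concatenate(out_imgs, axis=0), np.concatenate(out_labels, axis=0)
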