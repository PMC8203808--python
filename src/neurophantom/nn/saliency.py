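"""Guided-backpropagation saliency maps.

The map is the gradient of the *linear* (pre-softmax) target-class score
with respect to the input, computed with the guided rule at every ReLU:
the backward signal is zeroed wherever the forward activation or the
backward signal itself is negative. Subject maps are averaged over the
correctly classified patients only, then magnitudes below a fraction of
the maximum (one third by default) are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import AllConvNet


@dataclass
class SaliencyMap:
    data: np.ndarray
    source_ids: list = field(default_factory=list)
    threshold_fraction: float = 0.0


def guided_backprop_saliency(
    model: AllConvNet, image: np.ndarray, target_class: int = 1
) -> SaliencyMap:
    """Saliency of one (C, D, H, W) or (D, H, W) image; output matches input shape."""
    squeeze_channel = image.ndim == 3
    x = image[None, None] if squeeze_channel else image[None]
    model.guided_mode(True)
    try:
        logits = model.forward(x.astype(np.float32), training=False)
        dlogits = np.zeros_like(logits)
        dlogits[0, target_class] = 1.0  # linear score head: unit gradient
        dx = model.backward(dlogits)
    finally:
        model.guided_mode(False)
    sal = dx[0, 0] if squeeze_channel else dx[0]
    return SaliencyMap(data=np.asarray(sal, dtype=np.float64))


def average_saliency(
    maps: dict[str, SaliencyMap],
    correct_ids: list[str],
    threshold_fraction: float = 1.0 / 3.0,
) -> SaliencyMap:
    """Voxelwise mean over the listed subjects, then magnitude-thresholded."""
    if not correct_ids:
        raise ValueError("no correctly classified subjects to average over")
    stack = np.stack([maps[i].data for i in correct_ids])
    mean = stack.mean(axis=0)
    mag = np.abs(mean)
    cut = threshold_fraction * mag.max()
    out = np.where(mag >= cut, mean, 0.0)
    return SaliencyMap(data=out, source_ids=list(correct_ids),
                       threshold_fraction=threshold_fraction)
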