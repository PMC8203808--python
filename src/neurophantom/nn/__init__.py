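"""Self-contained numpy engine for the 3D all-convolutional classifier.

Implements exactly the layer set the architecture needs (3D convolution
with stride 1/2 and 'same' padding, dropout, batch normalization, ReLU,
global-average softmax head), Adam with the step-decay schedule, within-
class mixup augmentation, early stopping on validation AUC, and guided
backpropagation for saliency maps.
"""

from .network import NetworkSpec, AllConvNet, build_network, count_parameters, parameter_accountings
from .augment import AugmentConfig, mixup_augment
from .train import TrainConfig, train_cnn, lr_at_epoch, select_best_epoch, predict
from .saliency import SaliencyMap, guided_backprop_saliency, average_saliency

__all__ = [
    "NetworkSpec", "AllConvNet", "build_network", "count_parameters",
    "parameter_accountings", "AugmentConfig", "mixup_augment", "TrainConfig",
    "train_cnn", "lr_at_epoch", "select_best_epoch", "predict", "SaliencyMap",
    "guided_backprop_saliency", "average_saliency",
]
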