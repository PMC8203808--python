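"""Network builder, parameter accounting, mixup, training loop, saliency."""

import numpy as np
import pytest

from neurophantom.nn import (AugmentConfig, NetworkSpec, TrainConfig, build_network,
                             count_parameters, lr_at_epoch, mixup_augment, predict,
                             select_best_epoch, train_cnn)
from neurophantom.nn.layers import Conv3D
from neurophantom.nn.network import PAPER_FILTERS, parameter_accountings
from neurophantom.nn.saliency import average_saliency, guided_backprop_saliency


class TestBuildNetwork:
    def test_reference_architecture_structure(self):
        spec = NetworkSpec()
        net = build_network(spec, seed=0)
        convs = [l for l in net.layers if isinstance(l, Conv3D)]
        assert len(convs) == 14  # two per block
        widths = tuple(convs[2 * i].c_out for i in range(7))
        assert widths == PAPER_FILTERS
        strides = [c.stride for c in convs]
        assert strides == [1, 2] * 7

    def test_deterministic_initialization(self):
        a = build_network(NetworkSpec(), seed=3)
        b = build_network(NetworkSpec(), seed=3)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            assert np.array_equal(wa, wb)

    def test_wrong_block_count_rejected(self):
        with pytest.raises(ValueError, match="7 blocks"):
            NetworkSpec(filters=(16, 32, 32, 64, 64, 32))

    def test_wrong_ladder_rejected(self):
        with pytest.raises(ValueError, match="ladder"):
            NetworkSpec(filters=(8, 16, 16, 32, 32, 16, 8))

    def test_too_small_input_rejected(self):
        net = build_network(NetworkSpec(filters=(4, 4), strict=False), seed=0)
        with pytest.raises(ValueError, match="too small"):
            net.forward(np.zeros((1, 1, 2, 2, 2), dtype=np.float32))


class TestCountParameters:
    def test_one_block_toy_hand_sum(self):
        # biased convs 1->2 and 2->2, no BN, no head:
        # (27*1*2 + 2) + (27*2*2 + 2) = 166
        spec = NetworkSpec(filters=(2,), strict=False)
        accs = parameter_accountings(spec)
        assert accs["bias=on/bn=trainable/head=none"] - 2 * (2 + 2) == 166

    def test_closed_form_matches_built_model(self):
        for filters in [(2,), (3, 4), (4, 8, 8), PAPER_FILTERS,
                        (8, 16, 16, 8), (5, 7, 11)]:
            spec = NetworkSpec(filters=filters, strict=(filters == PAPER_FILTERS))
            net = build_network(spec, seed=0)
            assert count_parameters(spec) == net.n_parameters()

    def test_doubling_widths_quadruples_conv_weights(self):
        def conv_weights(filters):
            spec = NetworkSpec(filters=filters, strict=False, conv_bias=False)
            accs = parameter_accountings(spec)
            return accs["bias=off/bn=trainable/head=none"] - 2 * 2 * sum(filters)

        small = conv_weights((4, 8, 8))
        big = conv_weights((8, 16, 16))
        # exclude the input-layer term, which scales by 2 not 4
        in_small, in_big = 27 * 1 * 4, 27 * 1 * 8
        assert (big - in_big) == 4 * (small - in_small)


class TestMixup:
    def _imgs(self, n, value=None, rng=None):
        if value is not None:
            return np.full((n, 4, 4, 4), value, dtype=np.float32)
        return rng.standard_normal((n, 4, 4, 4)).astype(np.float32)

    def test_constant_images_give_exact_mixture(self):
        imgs = np.concatenate([self._imgs(2, 1.0), self._imgs(2, 0.0)])
        labels = np.array([0, 0, 0, 0])
        imgs[2:] = 0.0
        out, lab = mixup_augment(imgs, labels, AugmentConfig(per_class_target=50, seed=0))
        synth = out[4:]  # originals included first
        vals = np.unique(synth)
        candidates = np.array([0.0, 0.2, 0.8, 1.0])
        assert all(np.min(np.abs(candidates - v)) < 1e-6 for v in vals)
        # a ones+zeros pair mixes to exactly 0.8
        assert np.any(np.abs(vals - 0.8) < 1e-6)

    def test_exact_balanced_counts(self, rng):
        imgs = self._imgs(65, rng=rng)
        labels = np.array([0] * 40 + [1] * 25)
        out, lab = mixup_augment(imgs, labels, AugmentConfig(per_class_target=1000, seed=1))
        assert out.shape[0] == 2000
        assert (lab == 0).sum() == 1000 and (lab == 1).sum() == 1000

    def test_within_class_only_and_sources_distinct(self, rng):
        # encode class identity in the sign so any cross-class mix is detectable
        imgs = np.concatenate([np.abs(self._imgs(5, rng=rng)) + 1.0,
                               -np.abs(self._imgs(5, rng=rng)) - 1.0])
        labels = np.array([0] * 5 + [1] * 5)
        out, lab = mixup_augment(imgs, labels, AugmentConfig(per_class_target=100, seed=2))
        assert (out[lab == 0] > 0).all()
        assert (out[lab == 1] < 0).all()

    def test_deterministic_given_seed(self, rng):
        imgs = self._imgs(10, rng=rng)
        labels = np.array([0] * 5 + [1] * 5)
        cfg = AugmentConfig(per_class_target=30, seed=9)
        a, _ = mixup_augment(imgs, labels, cfg)
        b, _ = mixup_augment(imgs, labels, cfg)
        assert np.array_equal(a, b)

    def test_class_with_one_image_rejected(self, rng):
        imgs = self._imgs(3, rng=rng)
        with pytest.raises(ValueError, match="fewer than 2"):
            mixup_augment(imgs, np.array([0, 0, 1]), AugmentConfig(per_class_target=10))


class TestTrainingSchedule:
    def test_lr_step_decay(self):
        cfg = TrainConfig()
        assert lr_at_epoch(1, cfg) == pytest.approx(0.001)
        assert lr_at_epoch(11, cfg) == pytest.approx(0.0005)
        assert lr_at_epoch(25, cfg) == pytest.approx(0.00025)

    def test_early_stopping_on_scripted_history(self):
        # peak at epoch 5, then a plateau below it: stop at 25, keep epoch 5
        history = [0.6, 0.7, 0.8, 0.85, 0.9] + [0.88] * 30
        best, stop = select_best_epoch(history, patience=20)
        assert best == 5
        assert stop == 25

    def test_no_stop_before_patience(self):
        best, stop = select_best_epoch([0.5, 0.6, 0.7], patience=20)
        assert best == 3 and stop == 3


class TestTrainPredict:
    def _toy_volumes(self, n_per_class=20, shape=(10, 10, 10), effect=0.5, seed=0):
        """Blob phantoms with a strong implanted contrast; tiny and separable."""
        rng = np.random.default_rng(seed)
        base = rng.random(shape).astype(np.float32)
        xs, ys = [], []
        for cls in (0, 1):
            for i in range(n_per_class):
                img = base + 0.05 * rng.standard_normal(shape).astype(np.float32)
                if cls == 1:
                    img[2:6, 2:6, 2:6] *= (1.0 - effect)
                xs.append(img)
                ys.append(cls)
        return np.stack(xs)[:, None], np.array(ys)

    def test_learns_separable_toy_and_predicts(self):
        x, y = self._toy_volumes()
        rng = np.random.default_rng(5)
        order = rng.permutation(y.size)
        x, y = x[order], y[order]
        xtr, ytr, xval, yval = x[:32], y[:32], x[32:], y[32:]
        spec = NetworkSpec(filters=(4, 8), strict=False)
        net = build_network(spec, seed=1)
        cfg = TrainConfig(max_epochs=15, early_stop_patience=15, batch_size=8, seed=1)
        hist = train_cnn(net, xtr, ytr, xval, yval, cfg)
        assert hist["best_val_auc"] >= 0.95
        proba = predict(net, xval)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(yval, proba[:, 1]) >= 0.9

    def test_batch_equals_per_subject_prediction(self):
        x, _ = self._toy_volumes(n_per_class=3)
        net = build_network(NetworkSpec(filters=(4, 4), strict=False), seed=0)
        batch = net.predict_proba(x)
        singles = np.concatenate([net.predict_proba(x[i:i + 1]) for i in range(x.shape[0])])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_empty_validation_rejected(self):
        x, y = self._toy_volumes(n_per_class=3)
        net = build_network(NetworkSpec(filters=(4,), strict=False), seed=0)
        with pytest.raises(ValueError, match="validation"):
            train_cnn(net, x, y, x[:0], y[:0], TrainConfig())


class TestGuidedSaliency:
    def test_linear_single_conv_model_gradient(self):
        # bias-free single conv + GAP head: saliency of a linear model is the
        # correlation pattern of its kernel (same map for any input)
        spec = NetworkSpec(filters=(2,), strict=False, dropout_rate=0.0,
                           conv_bias=False)
        net = build_network(spec, seed=2)
        # make the model linear: disable the ReLUs
        for r in net._relus:
            r.forward = lambda x, training, r=r: (setattr(r, "_mask",
                                                  np.ones_like(x, dtype=bool)) or x)
        rng = np.random.default_rng(0)
        a = guided_backprop_saliency(net, rng.standard_normal((8, 8, 8)), 1)
        b = guided_backprop_saliency(net, rng.standard_normal((8, 8, 8)), 1)
        np.testing.assert_allclose(a.data, b.data, atol=1e-5)

    def test_zero_image_on_biasfree_model_gives_zero_map(self):
        spec = NetworkSpec(filters=(3, 3), strict=False, dropout_rate=0.0,
                           conv_bias=False)
        net = build_network(spec, seed=1)
        sal = guided_backprop_saliency(net, np.zeros((12, 12, 12)), 1)
        assert np.allclose(sal.data, 0.0)
        assert sal.data.shape == (12, 12, 12)

    def test_average_and_threshold(self):
        from neurophantom.nn.saliency import SaliencyMap

        m1 = SaliencyMap(np.array([[[1.0, 0.1]]]))
        m2 = SaliencyMap(np.array([[[-1.0, -0.1]]]))
        avg = average_saliency({"a": m1, "b": m2}, ["a", "b"])
        assert np.allclose(avg.data, 0.0)
        single = average_saliency({"a": m1}, ["a"], threshold_fraction=1 / 3)
        assert single.data[0, 0, 0] == 1.0
        assert single.data[0, 0, 1] == 0.0  # 0.1 < max/3
        nothr = average_saliency({"a": m1}, ["a"], threshold_fraction=0.0)
        assert nothr.data[0, 0, 1] == pytest.approx(0.1)

    def test_empty_id_list_rejected(self):
        from neurophantom.nn.saliency import SaliencyMap

        with pytest.raises(ValueError, match="no correctly classified"):
            average_saliency({"a": SaliencyMap(np.zeros((2, 2, 2)))}, [])
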