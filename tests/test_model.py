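"""Classifier architecture, gradients, training and score contracts.

Unit tests run the network on short 16 x 64 windows; nothing in the
architecture is tied to the production 1280-sample window except the
default spec, whose feature dimension is checked in closed form.
"""

import numpy as np
import pytest

from preictal import _nn
from preictal.model import (
    ConvNet,
    DivergenceError,
    EncoderSpec,
    HeadSpec,
    TrainConfig,
    build_encoder,
    load_bundle,
    predict_scores,
    save_bundle,
    train_generalizable,
)
from preictal.evaluate import auc

from conftest import make_toy_set

TINY_ENC = EncoderSpec(channels=(2, 3), conv_dropout=0.0)
TINY_HEAD = HeadSpec(kind="fc", fc_hidden=(8, 4), fc_dropout=0.0)
FAST_CFG = TrainConfig(seed=0, epochs=40, batch_size=16,
                       early_stop_patience=40, val_fraction=0.1)


class TestSpecs:
    def test_default_feature_dimension(self):
        # 16 x 1280 -> one 2x2/2 pool -> 8 x 640 with 32 filters
        assert EncoderSpec().feature_dim() == 32 * 8 * 640 == 163_840

    def test_three_conv_layers_rejected(self):
        with pytest.raises(ValueError):
            EncoderSpec(channels=(8, 16, 32))

    def test_fc_head_needs_two_hidden_layers(self):
        with pytest.raises(ValueError):
            HeadSpec(kind="fc", fc_hidden=(64,))

    def test_batch_norm_mandatory(self):
        with pytest.raises(ValueError):
            EncoderSpec(batch_norm=False)

    def test_encode_matches_feature_dim_formula(self):
        net = build_encoder(TINY_ENC, TINY_HEAD, n_channels=16, n_samples=64)
        x = np.random.default_rng(0).standard_normal((3, 1, 16, 64))
        feats = net.encode(x.astype(np.float32))
        assert feats.shape == (3, TINY_ENC.feature_dim(16, 64))

    def test_same_seed_identical_initialization(self):
        a = build_encoder(TINY_ENC, TINY_HEAD, 16, 64, seed=11)
        b = build_encoder(TINY_ENC, TINY_HEAD, 16, 64, seed=11)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        """Central-difference check of every parameter group."""
        net = ConvNet(TINY_ENC, TINY_HEAD, n_channels=4, n_samples=8, seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 1, 4, 8)).astype(np.float32)
        y = np.array([0, 1, 0, 1])

        def loss_fn():
            logits, _ = net.forward(x, train=True)
            return _nn.softmax_xent(logits, y)[0]

        logits, cache = net.forward(x, train=True)
        _, _, dlogits = _nn.softmax_xent(logits, y)
        grads = net.backward(dlogits, cache)
        # eps must stay below the typical distance of post-batch-norm
        # preactivations from the ReLU kink, or the difference quotient
        # measures the wrong one-sided slope
        eps = 1e-3
        for name, g in grads.items():
            p = net.params[name]
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = loss_fn()
                flat[idx] = orig - eps
                lo = loss_fn()
                flat[idx] = orig
                num = (hi - lo) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(
                    num, abs=2e-3, rel=5e-2), name


class TestTraining:
    def test_learns_separable_data(self):
        train = make_toy_set(n_per_class=48, seed=3)
        bundle = train_generalizable(train, FAST_CFG, TINY_HEAD, TINY_ENC)
        scores = predict_scores(bundle, train)
        acc = np.mean((scores > 0.5) == train.y)
        assert acc >= 0.95

    def test_label_shuffled_data_scores_at_chance(self):
        train = make_toy_set(n_per_class=48, seed=4, shuffle_labels=True)
        probe = make_toy_set(n_per_class=100, seed=5, shuffle_labels=True)
        bundle = train_generalizable(train, FAST_CFG, TINY_HEAD, TINY_ENC)
        acc = np.mean((predict_scores(bundle, probe) > 0.5) == probe.y)
        assert abs(acc - 0.5) <= 0.1

    def test_same_seed_identical_losses(self):
        train = make_toy_set(n_per_class=32, seed=6)
        a = train_generalizable(train, FAST_CFG, TINY_HEAD, TINY_ENC)
        b = train_generalizable(train, FAST_CFG, TINY_HEAD, TINY_ENC)
        assert a.train_meta["train_losses"] == b.train_meta["train_losses"]
        assert a.train_meta["val_losses"] == b.train_meta["val_losses"]

    def test_unbalanced_train_set_rejected(self):
        train = make_toy_set(n_per_class=20, seed=7)
        train.segments.pop()
        with pytest.raises(ValueError, match="unbalanced"):
            train_generalizable(train, FAST_CFG, TINY_HEAD, TINY_ENC)

    def test_test_split_rejected(self):
        test = make_toy_set(n_per_class=20, seed=8, split="test")
        with pytest.raises(ValueError, match="train"):
            train_generalizable(test, FAST_CFG, TINY_HEAD, TINY_ENC)

    def test_divergent_learning_rate_raises(self):
        train = make_toy_set(n_per_class=16, seed=9)
        cfg = TrainConfig(seed=0, epochs=3, batch_size=16, learning_rate=1e12)
        with pytest.raises((DivergenceError, FloatingPointError)):
            with np.errstate(over="raise", invalid="raise"):
                train_generalizable(train, cfg, TINY_HEAD, TINY_ENC)


class TestScores:
    def test_fc_scores_are_preictal_probabilities(self, toy_train_set):
        bundle = train_generalizable(toy_train_set, FAST_CFG, TINY_HEAD,
                                     TINY_ENC)
        probs = bundle.net.predict_proba(toy_train_set.X[:, None, :, :])
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert np.allclose(predict_scores(bundle, toy_train_set), probs[:, 1])

    def test_duplicated_segment_gets_identical_score(self, toy_train_set):
        bundle = train_generalizable(toy_train_set, FAST_CFG, TINY_HEAD,
                                     TINY_ENC)
        X = toy_train_set.X[:8]
        X2 = np.concatenate([X, X[:1]])
        s = predict_scores(bundle, X2)
        assert s[8] == s[0]

    def test_svm_head_shares_score_contract(self, toy_train_set):
        head = HeadSpec(kind="svm", fc_hidden=(8, 4), fc_dropout=0.0)
        bundle = train_generalizable(toy_train_set, FAST_CFG, head, TINY_ENC)
        probe = make_toy_set(n_per_class=60, seed=12)
        scores = predict_scores(bundle, probe)
        assert scores.shape == (len(probe),)
        assert auc(scores, probe.y) > 0.9

    def test_shape_mismatch_rejected(self, toy_train_set):
        bundle = train_generalizable(toy_train_set, FAST_CFG, TINY_HEAD,
                                     TINY_ENC)
        with pytest.raises(ValueError, match="shape"):
            predict_scores(bundle, np.zeros((2, 16, 128), np.float32))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, toy_train_set):
        head = HeadSpec(kind="svm", fc_hidden=(8, 4), fc_dropout=0.0)
        bundle = train_generalizable(toy_train_set, FAST_CFG, head, TINY_ENC)
        save_bundle(bundle, tmp_path / "m")
        back = load_bundle(tmp_path / "m")
        assert back.encoder_spec == bundle.encoder_spec
        assert back.head_spec == bundle.head_spec
        X = toy_train_set.X[:6]
        assert np.allclose(predict_scores(back, X), predict_scores(bundle, X))
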