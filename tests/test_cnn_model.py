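"""The convolutional classifier: elementary ops against naive oracles,
geometry arithmetic, loss closed forms, and training behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from venuerec.cnn_model import (
    CNNModel,
    ModelConfig,
    TrainingDiverged,
    conv_valid,
    cross_entropy_loss,
    layer_length_plan,
    maxpool2,
    prepare_dataset,
    softmax,
    train,
)
from conftest import small_config


# --- independent oracles (deliberately naive) --------------------------------

def naive_conv(inputs, kernel, bias=0.0):
    """Triple-loop valid convolution of one d-by-h kernel over an L-by-d input."""
    L, d = inputs.shape
    dk, h = kernel.shape
    out = np.zeros(L - h + 1)
    for i in range(L - h + 1):
        acc = bias
        for j in range(h):
            for c in range(d):
                acc += kernel[c, j] * inputs[i + j, c]
        out[i] = acc
    return out


def naive_maxpool2(v):
    return np.array([max(v[2 * i], v[2 * i + 1]) for i in range(len(v) // 2)])


class TestConvValid:
    def test_output_length(self):
        inputs = np.zeros((350, 4))
        maps = conv_valid(inputs, [np.zeros((4, 3))])
        assert maps[0].shape == (348,)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            inputs = rng.normal(size=(20, 8))
            kernels = [rng.normal(size=(8, h)) for h in (3, 4, 5)]
            biases = rng.normal(size=3)
            maps = conv_valid(inputs, kernels, biases, activation=None)
            for fmap, kern, b in zip(maps, kernels, biases):
                assert np.allclose(fmap, naive_conv(inputs, kern, b), atol=1e-5)

    def test_sliding_window_sums_with_ones_kernel(self):
        inputs = np.zeros((6, 1))
        inputs[2, 0] = 1.0  # one-hot input
        maps = conv_valid(inputs, [np.ones((1, 3))], activation=None)
        assert np.allclose(maps[0], [1, 1, 1, 0])

    def test_relu_clamps_negative_preactivations(self):
        inputs = -np.ones((5, 2))
        maps = conv_valid(inputs, [np.ones((2, 2))])
        assert np.array_equal(maps[0], np.zeros(4))

    def test_window_longer_than_input_rejected(self):
        with pytest.raises(ValueError):
            conv_valid(np.zeros((2, 3)), [np.zeros((3, 5))])


class TestMaxpool2:
    def test_examples(self):
        assert np.array_equal(maxpool2([1, 3, 2, 5]), [3, 5])
        assert maxpool2(np.arange(171)).shape == (85,)
        assert np.array_equal(maxpool2(np.full(7, 2.5)), np.full(3, 2.5))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            maxpool2([1.0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_naive_pairwise_max(self, values):
        assert np.array_equal(maxpool2(values), naive_maxpool2(values))


class TestLayerLengthPlan:
    def test_reference_geometry(self):
        plan = layer_length_plan(ModelConfig())
        assert plan == [(348, 174), (171, 85), (81, 40)]
        assert ModelConfig().n_features == 96 * 40 == 3840

    def test_matches_independent_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = int(rng.integers(50, 500))
            windows = [int(h) for h in rng.integers(2, 8, size=3)]
            plan = layer_length_plan(m=m, windows=windows)
            length = m
            for (conv_len, pooled), h in zip(plan, windows):
                assert conv_len == length - h + 1
                assert pooled == conv_len // 2
                length = pooled

    def test_error_names_offending_stage(self):
        with pytest.raises(ValueError, match="stage"):
            layer_length_plan(m=10, windows=(3, 4, 5))

    def test_unpoolable_single_position_rejected(self):
        with pytest.raises(ValueError, match="max-pool"):
            layer_length_plan(m=5, windows=(5,))


class TestSoftmaxAndLoss:
    def test_uniform_over_constant_scores(self):
        assert np.allclose(softmax(np.zeros(4)), [0.25] * 4)

    def test_closed_form_two_class(self):
        assert np.allclose(softmax(np.array([math.log(2), 0.0])), [2 / 3, 1 / 3])

    @given(st.lists(st.floats(-1e300, 1e300, allow_nan=False), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalizes_even_for_huge_scores(self, z):
        S = softmax(np.array(z))
        assert np.isclose(S.sum(), 1.0, atol=1e-6)
        assert np.all(S >= 0) and np.all(S <= 1)

    def test_confident_prediction_near_zero_loss(self):
        S = np.array([1e-7, 1 - 2e-7, 1e-7])
        Y = np.array([0.0, 1.0, 0.0])
        assert cross_entropy_loss(S, Y) < 1e-5

    @pytest.mark.parametrize("T", [2, 5, 60])
    def test_uniform_prediction_costs_ln_T(self, T):
        S = np.full(T, 1.0 / T)
        Y = np.zeros(T)
        Y[T // 2] = 1.0
        assert np.isclose(cross_entropy_loss(S, Y), math.log(T))

    def test_matches_formula_oracle_with_l2(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            z = rng.normal(size=6)
            S = np.exp(z) / np.exp(z).sum()
            Y = np.zeros(6)
            Y[rng.integers(6)] = 1.0
            w = rng.normal(size=(3, 4))
            expected = -sum(Y[i] * math.log(S[i]) for i in range(6))
            expected += 0.01 * sum(w[a, b] ** 2 for a in range(3) for b in range(4))
            got = cross_entropy_loss(S, Y, l2_coefficient=0.01, weights=[w])
            assert np.isclose(got, expected, atol=1e-10)

    def test_non_one_hot_target_rejected(self):
        S = np.full(3, 1 / 3)
        with pytest.raises(ValueError):
            cross_entropy_loss(S, np.array([0.5, 0.5, 0.0]))
        with pytest.raises(ValueError):
            cross_entropy_loss(S, np.array([1.0, 1.0, 0.0]))


def _tiny_model(n_classes=4, seed=0, **overrides):
    cfg = small_config(n_classes=n_classes, seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    E = rng.normal(0, 0.1, size=(30, cfg.k))
    E[0] = 0
    return CNNModel(cfg, E, [f"J{i}" for i in range(n_classes)]), cfg


class TestForward:
    def test_untrained_head_predicts_uniform(self):
        model, cfg = _tiny_model(n_classes=4)
        ids = np.arange(1, cfg.m + 1) % 29 + 1
        scores = model.forward(ids)
        assert np.allclose(scores.S, 0.25)
        assert np.allclose(scores.z, 0.0)

    def test_probabilities_sum_to_one_and_below_one(self):
        model, cfg = _tiny_model(n_classes=7)
        rng = np.random.default_rng(3)
        batch = rng.integers(0, 30, size=(16, cfg.m))
        S = model.forward(batch)
        assert np.allclose(S.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(S < 1.0)

    def test_inference_is_deterministic_without_dropout(self):
        model, cfg = _tiny_model()
        ids = np.random.default_rng(5).integers(0, 30, size=cfg.m)
        s1 = model.forward(ids)
        s2 = model.forward(ids)
        assert np.array_equal(s1.S, s2.S)  # bitwise: dropout off at inference

    def test_shape_mismatch_rejected(self):
        model, _ = _tiny_model()
        with pytest.raises(ValueError):
            model.forward(np.zeros((10, 7)))

    def test_global_max_pool_option_reduces_features(self):
        cfg = small_config(n_classes=3, global_max_pool=True)
        assert cfg.n_features == cfg.conv_stages[-1][0]
        rng = np.random.default_rng(0)
        E = rng.normal(0, 0.1, size=(30, cfg.k))
        model = CNNModel(cfg, E, ["a", "b", "c"])
        S = model.forward(rng.integers(0, 30, size=(4, cfg.m)))
        assert S.shape == (4, 3)


class TestTraining:
    def test_same_seed_reproduces_final_loss(self, separable_corpus):
        _, records, _ = separable_corpus
        losses = []
        for _ in range(2):
            cfg = small_config(n_classes=5, seed=13, max_epochs=3)
            from venuerec.pipeline import fit_model

            model, _vocab = fit_model(records, config=cfg)
            losses.append(model.history[-1]["loss"])
        assert abs(losses[0] - losses[1]) < 1e-9

    def test_epoch_zero_batch_loss_is_ln_T(self, separable_corpus):
        # with a zero-initialised head the first forward pass is uniform
        _, records, _ = separable_corpus
        cfg = small_config(n_classes=5, seed=0)
        labels = sorted({r.journal_label for r in records})
        from venuerec.text_prep import build_vocabulary, tokenize

        vocab = build_vocabulary(tokenize(r.abstract_text) for r in records)
        rng = np.random.default_rng(0)
        E = rng.normal(0, 0.1, size=(max(vocab.values()) + 1, cfg.k))
        model = CNNModel(cfg, E, labels)
        ids, y = prepare_dataset(records[:20], vocab, labels, m=cfg.m)
        S = model.forward(ids)
        batch_ce = -np.log(S[np.arange(len(y)), y]).mean()
        assert np.isclose(batch_ce, math.log(5), atol=1e-12)

    def test_overfits_separable_data(self, overfit_run):
        model, _, _ = overfit_run
        assert model.history[-1]["train_acc"] >= 0.99
        assert len(model.history) <= 200

    def test_loss_decreases_during_overfit(self, overfit_run):
        model, _, _ = overfit_run
        losses = [h["loss"] for h in model.history[:10]]
        assert losses[-1] < losses[0]
        drops = sum(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))
        assert drops >= 0.8 * (len(losses) - 1)

    def test_nan_loss_aborts_with_diagnostic(self):
        model, cfg = _tiny_model(n_classes=4)
        model.params["W1"][:] = np.nan
        rng = np.random.default_rng(1)
        ids = rng.integers(1, 30, size=(16, cfg.m)).astype(np.int32)
        y = rng.integers(0, 4, size=16)
        with pytest.raises(TrainingDiverged):
            train(model, ids, y, epochs=1)

    def test_labels_out_of_range_rejected(self):
        model, cfg = _tiny_model(n_classes=4)
        ids = np.ones((4, cfg.m), dtype=np.int32)
        with pytest.raises(ValueError):
            train(model, ids, np.array([0, 1, 2, 7]), epochs=1)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, overfit_run):
        model, vocab, records = overfit_run
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = CNNModel.load(path)
        assert loaded.class_labels == model.class_labels
        assert loaded.vocab_hash == model.vocab_hash
        ids, _ = prepare_dataset(records[:8], vocab, model.class_labels, m=model.config.m)
        assert np.array_equal(model.forward(ids), loaded.forward(ids))

    def test_unrecognised_format_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        meta = np.frombuffer(b'{"format": "something-else"}', dtype=np.uint8)
        np.savez(path, __meta__=meta)
        with pytest.raises(ValueError, match="format"):
            CNNModel.load(path)
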