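"""Classifier tests: crop/pad, architecture constants, splitting, training
mechanics, gradients, evaluation and inference."""

import numpy as np
import pytest

import morphoflow as mf
from morphoflow import cnn
from morphoflow.cnn import (ClassifierConfig, ClassifierModel, DenseNetSmall,
                            _loss_and_grads, build_network, classify,
                            crop_pad_32, evaluate, merge_classes,
                            split_dataset, train)


class TestCropPad:
    def test_matching_input_is_identity(self):
        x = np.random.default_rng(0).uniform(size=(32, 32, 3))
        assert np.array_equal(crop_pad_32(x), x)

    def test_mixed_crop_and_pad_geometry(self):
        x = np.ones((40, 25, 3))
        out = crop_pad_32(x)
        assert out.shape == (32, 32, 3)
        # 25-axis zero-padded (3, 4); 40-axis center-cropped (4, 4)
        assert np.all(out[:, :3] == 0) and np.all(out[:, -4:] == 0)
        assert np.all(out[:, 3:28] == 1)

    def test_single_pixel_lands_at_15_15(self):
        out = crop_pad_32(np.ones((1, 1, 3)))
        assert out.shape == (32, 32, 3)
        nz = np.argwhere(out[:, :, 0])
        assert nz.tolist() == [[15, 15]]

    @pytest.mark.parametrize("shape", [(1, 1), (17, 64), (100, 100), (32, 33)])
    def test_any_input_size_accepted(self, shape):
        assert crop_pad_32(np.zeros(shape + (3,))).shape == (32, 32, 3)


class TestArchitecture:
    def test_flatten_length_and_final_feature_maps(self):
        model = build_network(7)
        assert model.net.flatten_length == 1392
        assert model.net.params["fc_W"].shape == (1392, 7)
        # final transition produces 87 feature maps on a 4x4 grid
        assert model.net.config.transition_channels[-1] == 87

    def test_spatial_path_halves_three_times(self):
        model = build_network(3)
        x = np.zeros((1, 32, 32, 3), np.float32)
        logits, cache = model.net.forward(x, keep_cache=True)
        assert cache["pre_flat_shape"] == (1, 4, 4, 87)

    def test_zero_image_gives_finite_softmax_summing_to_one(self):
        model = build_network(5)
        model.channel_scale = np.ones(3, np.float32)
        probs = model.predict_proba(np.zeros((2, 32, 32, 3), np.float32))
        assert np.all(np.isfinite(probs))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="87"):
            ClassifierConfig(transition_channels=(8, 16, 64))
        with pytest.raises(ValueError, match="32x32x3"):
            ClassifierConfig(input_size=(28, 28, 3))
        with pytest.raises(ValueError, match="sum to 1"):
            ClassifierConfig(split=(0.7, 0.2, 0.2))
        with pytest.raises(ValueError, match="classes"):
            build_network(1)

    def test_backward_matches_numerical_gradient(self):
        """Float64 finite-difference check of the hand-written backprop
        through dense concatenation, strided transitions and the FC head."""
        net = DenseNetSmall(3, ClassifierConfig(seed=1))
        net.params = {k: v.astype(np.float64) for k, v in net.params.items()}
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 32, 32, 3))
        y = np.array([0, 1, 2])
        _, _, _, grads = _loss_and_grads(net, x, y, 1e-4)
        for name in ("b0l0_W", "b1l1_W", "b2t_W", "fc_W", "b0t_b"):
            p = net.params[name]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps, orig = 1e-6, p[idx]
            p[idx] = orig + eps
            lp, _, _, _ = _loss_and_grads(net, x, y, 1e-4)
            p[idx] = orig - eps
            lm, _, _, _ = _loss_and_grads(net, x, y, 1e-4)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=1e-3, abs=1e-9)


class TestMergeClasses:
    def test_nine_clusters_with_two_merges_give_seven_classes(self):
        ids = [f"Pc{i}" for i in range(1, 10)]
        merge = {c: c for c in ids}
        merge["Pc9"] = "Pc1_CT"
        merge["Pc1"] = "Pc1_CT"
        merge["Pc8"] = "Pc5_CT"
        merge["Pc5"] = "Pc5_CT"
        labels, classes = merge_classes(np.array(ids), merge)
        assert len(classes) == 7
        assert labels[0] == labels[8]   # Pc1 and Pc9 share a class
        assert labels[4] == labels[7]   # Pc5 and Pc8 share a class

    def test_identity_map_preserves_class_count(self):
        labels, classes = merge_classes(np.array([3, 1, 2, 1]))
        assert len(classes) == 3

    def test_empty_input(self):
        labels, classes = merge_classes(np.array([], dtype=int))
        assert len(labels) == 0 and classes == []

    def test_unmapped_id_raises(self):
        with pytest.raises(ValueError, match="without a class mapping"):
            merge_classes(np.array([1, 2]), {1: "a"})


class TestSplit:
    def test_split_sizes_and_partition(self):
        labels = np.repeat([0, 1, 2, 3], 250)
        tr, te, va = split_dataset(labels, (0.8, 0.1, 0.1), seed=4)
        assert abs(len(tr) - 800) <= 4 and abs(len(te) - 100) <= 4
        all_idx = np.concatenate([tr, te, va])
        assert len(np.unique(all_idx)) == 1000 == len(all_idx)

    def test_stratification_per_class(self):
        labels = np.array([0] * 900 + [1] * 100)
        tr, te, va = split_dataset(labels, (0.8, 0.1, 0.1), seed=0)
        assert (labels[te] == 1).sum() in (9, 10, 11)

    def test_same_seed_identical_split(self):
        labels = np.repeat([0, 1], 50)
        a = split_dataset(labels, seed=9)
        b = split_dataset(labels, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            split_dataset(np.array([0, 0, 0, 1, 1]))


def _toy_images(rng, n_per=40):
    """Two trivially separable classes: bright top half vs bright bottom."""
    xs, ys = [], []
    for c in range(2):
        img = np.zeros((n_per, 32, 32, 3), np.float32)
        if c == 0:
            img[:, :16] = 1.0
        else:
            img[:, 16:] = 1.0
        img += rng.normal(0, 0.05, img.shape).astype(np.float32)
        xs.append(img)
        ys.append(np.full(n_per, c))
    return np.concatenate(xs), np.concatenate(ys)


class TestTraining:
    def test_log_has_one_entry_per_interval_and_learns(self):
        rng = np.random.default_rng(0)
        x, y = _toy_images(rng)
        cfg = ClassifierConfig(iterations=300, batch_size=16, seed=0,
                               eval_interval=100)
        model = build_network(2, cfg)
        train(model, x, y, x[:20], y[:20], cfg)
        assert len(model.training_log) == 3
        assert model.training_log[-1]["test_acc"] >= 0.95
        # stepwise decaying learning rate
        assert model.training_log[-1]["learning_rate"] < cfg.learning_rate

    def test_huge_l2_collapses_weights_to_chance(self):
        rng = np.random.default_rng(1)
        x, y = _toy_images(rng)
        cfg = ClassifierConfig(iterations=200, batch_size=16, seed=0,
                               l2=10.0, eval_interval=100)
        model = build_network(2, cfg)
        train(model, x, y, x[:20], y[:20], cfg)
        w_norm = float(np.abs(model.net.params["fc_W"]).max())
        assert w_norm < 1e-2
        probs = model.predict_proba(x[:10])
        assert np.allclose(probs, 0.5, atol=0.05)

    def test_missing_training_class_rejected(self):
        rng = np.random.default_rng(2)
        x, y = _toy_images(rng)
        cfg = ClassifierConfig(iterations=10, batch_size=8, seed=0)
        model = build_network(2, cfg)
        with pytest.raises(ValueError, match="absent"):
            train(model, x[y == 0], y[y == 0], x, y, cfg)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        x, y = _toy_images(rng)
        cfg = ClassifierConfig(iterations=100, batch_size=16, seed=0)
        model = build_network(2, cfg)
        train(model, x, y, x[:20], y[:20], cfg)
        model.save(tmp_path / "w.npz", tmp_path / "m.json")
        back = ClassifierModel.load(tmp_path / "w.npz", tmp_path / "m.json")
        assert np.allclose(back.predict_proba(x[:5]), model.predict_proba(x[:5]))


class TestEvaluateClassify:
    class _StubModel(ClassifierModel):
        """Fixed-probability model for metric-path tests."""

        def __init__(self, probs):
            self._probs = probs
            self.class_labels = list(range(probs.shape[1]))

        def predict_proba(self, stacks, chunk=512):
            return self._probs[: len(stacks)]

    def test_perfect_predictions_score_one(self):
        y = np.repeat([0, 1, 2], 10)
        probs = np.eye(3)[y]
        res = evaluate(self._StubModel(probs), np.zeros((30, 32, 32, 3)), y)
        assert np.allclose(res["precision"], 1.0)
        assert np.allclose(res["f1"], 1.0)
        assert res["weighted_f1"] == 1.0
        assert np.allclose(res["true_match_probability"], 1.0)

    def test_hand_computed_confusion_precision(self):
        # confusion [[5,0,0],[1,4,0],[0,0,5]] -> precision (5/6, 1, 1)
        y = np.repeat([0, 1, 2], 5)
        preds = np.array([0] * 5 + [0] + [1] * 4 + [2] * 5)
        probs = np.eye(3)[preds]
        res = evaluate(self._StubModel(probs), np.zeros((15, 32, 32, 3)), y)
        assert np.allclose(res["precision"], [5 / 6, 1.0, 1.0])
        assert np.array_equal(res["confusion"],
                              [[5, 0, 0], [1, 4, 0], [0, 0, 5]])

    def test_uniform_random_predictor_accuracy_near_chance(self):
        rng = np.random.default_rng(5)
        n, c = 1000, 4
        probs = rng.dirichlet(np.ones(c), size=n)
        y = rng.integers(0, c, n)
        res = evaluate(self._StubModel(probs), np.zeros((n, 32, 32, 3)), y)
        # binomial oracle: accuracy ~ Bin(n, 1/c)/n
        se = np.sqrt((1 / c) * (1 - 1 / c) / n)
        assert abs(res["accuracy"] - 1 / c) < 4 * se

    def test_classify_probability_vectors_sum_to_one(self):
        model = build_network(3)
        model.channel_scale = np.ones(3, np.float32)
        out = classify(model, np.random.default_rng(6)
                       .uniform(size=(8, 32, 32, 3)).astype(np.float32))
        assert np.allclose(out["probabilities"].sum(axis=1), 1.0, atol=1e-6)
        assert out["probabilities"].shape == (8, 3)
        assert len(out["classes"]) == 8
        assert 0.0 <= out["reliability"]["fraction_confident"] <= 1.0

    def test_classify_single_event(self):
        model = build_network(4)
        model.channel_scale = np.ones(3, np.float32)
        out = classify(model, np.zeros((1, 32, 32, 3), np.float32))
        assert out["probabilities"].shape == (1, 4)

    def test_channel_mismatch_rejected(self):
        model = build_network(3)
        with pytest.raises(ValueError, match="channel"):
            model.predict_proba(np.zeros((2, 32, 32, 5), np.float32))
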