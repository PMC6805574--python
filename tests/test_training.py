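import copy

import numpy as np
import pytest

from histocnn.network import SmallSENet
from histocnn.tiling import TilingSpec
from histocnn.training import (
    HybridClassifier,
    TrainConfig,
    TrainingDivergedError,
    ensemble_predict,
    image_to_tensor,
    predict_hybrid,
    predict_local,
    predictions_frame,
    train_branch,
    vote,
)


def _two_class_blobs(rng, n=20, side=8):
    """Tiny separable dataset: class differs by channel mean."""
    y = np.arange(n) % 2
    x = rng.standard_normal((n, 3, side, side)) * 0.3
    x[y == 1] += 0.8
    return x, y


class TestTrainConfig:
    def test_reference_protocol_defaults(self):
        cfg = TrainConfig()
        assert cfg.batch_size == 10
        assert cfg.initial_lr == 0.0004
        assert cfg.momentum == 0.9
        assert cfg.weight_decay == 0.009
        assert cfg.iterations == 40000
        assert cfg.lr_decay_every == 10000

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(initial_lr=-1)


class TestTrainBranch:
    def test_zero_lr_leaves_parameters(self, rng):
        model = SmallSENet(seed=0)
        snapshot = [p.value.copy() for p in model.parameters()]
        x, y = _two_class_blobs(rng)
        train_branch(model, x, y, TrainConfig.desk(iterations=20, initial_lr=0.0,
                                                   batch_size=5))
        for p, s in zip(model.parameters(), snapshot):
            np.testing.assert_array_equal(p.value, s)

    def test_seed_determinism(self, rng):
        x, y = _two_class_blobs(rng)
        traces = []
        for _ in range(2):
            model = SmallSENet(seed=3)
            cfg = TrainConfig.desk(iterations=30, batch_size=5, seed=11)
            traces.append(train_branch(model, x, y, cfg))
        np.testing.assert_array_equal(traces[0], traces[1])

    def test_divergence_aborts(self, rng):
        model = SmallSENet(seed=0)
        next(model.parameters()).value[0] = np.nan
        x, y = _two_class_blobs(rng)
        with pytest.raises(TrainingDivergedError):
            train_branch(model, x, y, TrainConfig.desk(iterations=5, batch_size=5))

    def test_overfit_20_samples(self, rng):
        # stochastic contract: majority of 3 seeds reach 100% training accuracy
        passes = 0
        for seed in range(3):
            data_rng = np.random.default_rng(100 + seed)
            x, y = _two_class_blobs(data_rng)
            model = SmallSENet(c1=8, c2=8, seed=seed)
            cfg = TrainConfig.desk(iterations=300, batch_size=5, initial_lr=0.05,
                                   seed=seed)
            train_branch(model, x, y, cfg)
            pred = model.forward(x, train=False).argmax(axis=1)
            passes += int((pred == y).mean() == 1.0)
        assert passes >= 2

    def test_empty_input_rejected(self):
        model = SmallSENet(seed=0)
        with pytest.raises(ValueError):
            train_branch(model, np.zeros((0, 3, 8, 8)), np.zeros(0),
                         TrainConfig.desk(iterations=1))

    def test_loss_trace_length(self, rng):
        model = SmallSENet(seed=0)
        x, y = _two_class_blobs(rng)
        trace = train_branch(model, x, y,
                             TrainConfig.desk(iterations=17, batch_size=5))
        assert len(trace) == 17


class TestVoting:
    def test_sum_rule_mean(self):
        p = vote([(0.9, 0.1), (0.5, 0.5), (0.1, 0.9)], "sum")
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_identical_predictions_either_rule(self):
        for rule in ("sum", "max"):
            p = vote([(0.7, 0.3)] * 5, rule)
            np.testing.assert_allclose(p, [0.7, 0.3])

    def test_max_rule_majority(self):
        # labels {1, 1, 0} -> class 1
        p = vote([(0.2, 0.8), (0.4, 0.6), (0.9, 0.1)], "max")
        assert np.argmax(p) == 1

    def test_max_rule_tie_falls_back_to_sum(self):
        p = vote([(0.9, 0.1), (0.2, 0.8)], "max")
        np.testing.assert_allclose(p, [0.55, 0.45])

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            vote([(0.5, 0.5)], "product")

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            vote([], "sum")

    def test_simplex_preserved(self, rng):
        for _ in range(20):
            raw = rng.uniform(0.01, 1, (5, 3))
            probs = raw / raw.sum(axis=1, keepdims=True)
            for rule in ("sum", "max"):
                assert abs(vote(list(probs), rule).sum() - 1.0) < 1e-6


class TestPredictLocal:
    def test_patch_voting(self, rng):
        model = SmallSENet(seed=0)
        patches = rng.standard_normal((4, 3, 8, 8))
        p = predict_local(model, patches, "sum")
        direct = model.forward(patches, train=False).mean(axis=0)
        np.testing.assert_allclose(p, direct)

    def test_empty_patches(self):
        with pytest.raises(ValueError):
            predict_local(SmallSENet(seed=0), [])


class TestPredictHybrid:
    def test_direct_substitution(self):
        p = predict_hybrid([1.0, 0.0], [0.0, 1.0], 0.6)
        np.testing.assert_allclose(p, [0.6, 0.4])

    def test_lambda_extremes(self):
        np.testing.assert_allclose(predict_hybrid([0.8, 0.2], [0.3, 0.7], 1.0),
                                   [0.8, 0.2])
        np.testing.assert_allclose(predict_hybrid([0.8, 0.2], [0.3, 0.7], 0.0),
                                   [0.3, 0.7])

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            predict_hybrid([1, 0], [0, 1], 1.5)

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            predict_hybrid([0.9, 0.3], [0.5, 0.5], 0.5)

    def test_simplex_membership(self, rng):
        for _ in range(20):
            a = rng.dirichlet([1, 1])
            b = rng.dirichlet([1, 1])
            lam = float(rng.uniform(0, 1))
            assert abs(predict_hybrid(a, b, lam).sum() - 1.0) < 1e-6


class _FixedModel:
    def __init__(self, p):
        self.p = np.asarray(p, dtype=float)

    def predict_proba(self, image):
        return self.p


class TestEnsemble:
    def test_identical_models_invariant(self):
        models = [_FixedModel([0.7, 0.3])] * 5
        for rule in ("sum", "max"):
            fused, label = ensemble_predict(models, None, rule)
            np.testing.assert_allclose(fused, [0.7, 0.3])
            assert label == 0

    def test_sum_rule_arithmetic(self):
        probs = [(0.8, 0.2), (0.6, 0.4), (0.4, 0.6), (0.9, 0.1), (0.3, 0.7)]
        fused, label = ensemble_predict([_FixedModel(p) for p in probs], None, "sum")
        np.testing.assert_allclose(fused, [0.6, 0.4])
        assert label == 0

    def test_max_rule_majority(self):
        # per-model labels {0, 0, 1, 1, 1} -> 1
        probs = [(0.8, 0.2), (0.6, 0.4), (0.4, 0.6), (0.1, 0.9), (0.3, 0.7)]
        _, label = ensemble_predict([_FixedModel(p) for p in probs], None, "max")
        assert label == 1

    def test_empty_model_list(self):
        with pytest.raises(ValueError):
            ensemble_predict([], None)


class TestHybridClassifier:
    def test_fusion_path(self, rng):
        spec = TilingSpec(resize_to=None, patch_side=8, global_input_side=8)
        clf = HybridClassifier(SmallSENet(seed=0), SmallSENet(seed=1), spec,
                               lam=0.6)
        image = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        p = clf.predict_proba(image)
        assert p.shape == (2,)
        assert abs(p.sum() - 1.0) < 1e-6
        assert clf.predict(image) in (0, 1)

    def test_lambda_one_matches_local_only(self, rng):
        spec = TilingSpec(resize_to=None, patch_side=8, global_input_side=8)
        local = SmallSENet(seed=1)
        clf = HybridClassifier(SmallSENet(seed=0), local, spec, lam=1.0)
        image = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        from histocnn.tiling import tile
        patches = np.stack([image_to_tensor(p) for p in tile(image, spec)])
        np.testing.assert_allclose(clf.predict_proba(image),
                                   predict_local(local, patches, "sum"))


def test_image_to_tensor_range(rng):
    img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
    t = image_to_tensor(img)
    assert t.shape == (3, 8, 8)
    assert t.min() >= -0.5 and t.max() <= 0.5


def test_predictions_frame(cohort_manifest):
    recs = cohort_manifest.records[:3]
    probs = [[0.9, 0.1], [0.2, 0.8], [0.5, 0.5]]
    df = predictions_frame(recs, probs, cohort_manifest.class_names)
    assert list(df.columns) == ["path", "patient_id", "true_label",
                                "P_benign", "P_malignant", "pred_label"]
    assert df["pred_label"].tolist() == ["benign", "malignant", "benign"]
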