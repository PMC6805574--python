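import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histocnn.network import ArchitectureSpec, SmallSENet, build_model, \
    count_params_flops
from histocnn.pruning import (
    ChannelImportance,
    PruneMask,
    PruneSchedule,
    ThresholdRule,
    accumulate_importance,
    apply_pruning,
    per_loop_proportion,
    plan_masks,
    prune_retrain_loop,
    select_by_threshold,
    select_prune_set,
)
from histocnn.training import TrainConfig


class TestPerLoopProportion:
    def test_half_in_one_loop(self):
        assert per_loop_proportion(0.5, 1) == 0.5

    @pytest.mark.parametrize("r,printed", [(1, 0.80), (2, 0.55), (3, 0.42), (4, 0.33)])
    def test_reference_schedule_at_80_percent(self, r, printed):
        assert round(per_loop_proportion(0.8, r), 2) == printed

    def test_zero_target(self):
        for r in (1, 3, 7):
            assert per_loop_proportion(0.0, r) == 0.0

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            per_loop_proportion(1.0, 2)
        with pytest.raises(ValueError):
            per_loop_proportion(-0.1, 2)
        with pytest.raises(ValueError):
            per_loop_proportion(0.5, 0)

    @given(o=st.floats(0.0, 0.999), r=st.integers(1, 20))
    @settings(max_examples=100, deadline=None)
    def test_geometric_series_identity(self, o, r):
        # sum_{i=1..R} (1-X)^(i-1) X == O
        x = per_loop_proportion(o, r)
        total = sum((1 - x) ** i * x for i in range(r))
        assert abs(total - o) < 1e-12


class _StubBlock:
    def __init__(self):
        self.record = False
        self.last_s = None


class _StubModel:
    """Replays a scripted sequence of per-sample activation factors."""

    def __init__(self, script):
        self.script = np.asarray(script, dtype=float)
        self._cursor = 0
        self.block = _StubBlock()

    def se_layers(self):
        return {"L": self.block}

    def forward(self, batch, train=True):
        n = batch.shape[0]
        self.block.last_s = self.script[self._cursor : self._cursor + n]
        self._cursor += n


class TestAccumulateImportance:
    def test_identical_samples(self):
        model = _StubModel([[0.3, 0.7]] * 5)
        imp = accumulate_importance(model, np.zeros((5, 1, 2, 2)))
        np.testing.assert_allclose(imp["L"].w, [0.3, 0.7])
        assert imp["L"].n_samples == 5

    def test_forced_two_sample_mean(self):
        model = _StubModel([[0.2, 0.8], [0.4, 0.6]])
        imp = accumulate_importance(model, np.zeros((2, 1, 2, 2)))
        np.testing.assert_allclose(imp["L"].w, [0.3, 0.7])

    def test_streaming_equals_stacked_batch(self, rng):
        model = SmallSENet(c1=6, c2=6, seed=2)
        samples = rng.standard_normal((10, 3, 8, 8))
        stacked = accumulate_importance(model, samples)
        streamed = accumulate_importance(model, iter(samples), batch_size=1)
        for name in stacked:
            np.testing.assert_allclose(streamed[name].w, stacked[name].w, atol=1e-7)

    def test_empty_stream_errors(self):
        model = SmallSENet(seed=0)
        with pytest.raises(ValueError, match="empty"):
            accumulate_importance(model, iter([]))

    def test_importance_in_unit_interval(self, rng):
        model = SmallSENet(c1=6, c2=6, seed=2)
        imp = accumulate_importance(model, rng.standard_normal((4, 3, 8, 8)))
        for v in imp.values():
            assert np.all((v.w > 0) & (v.w < 1))


def _brute_force_prune(w, x):
    """Independent oracle: full sort of (importance, index) pairs."""
    c = len(w)
    n_prune = min(c - 1, int(np.floor(x * c + 0.5)))
    ranked = sorted(range(c), key=lambda i: (w[i], i))
    pruned = set(ranked[:n_prune])
    return sorted(i for i in range(c) if i not in pruned)


class TestSelectPruneSet:
    def test_worked_example(self):
        imp = ChannelImportance("L", [0.1, 0.4, 0.2, 0.3], 1)
        mask = select_prune_set(imp, 0.5)
        assert mask.kept_indices.tolist() == [1, 3]
        assert mask.n_kept == 2

    def test_zero_proportion_keeps_all(self):
        imp = ChannelImportance("L", [0.5, 0.6, 0.7], 1)
        assert select_prune_set(imp, 0.0).kept_indices.tolist() == [0, 1, 2]

    def test_min_one_channel_floor(self):
        imp = ChannelImportance("L", [0.5], 1)
        assert select_prune_set(imp, 0.9).kept_indices.tolist() == [0]

    def test_ties_prune_lower_index_first(self):
        imp = ChannelImportance("L", [0.5, 0.5, 0.5, 0.9], 1)
        mask = select_prune_set(imp, 0.5)
        assert mask.kept_indices.tolist() == [2, 3]

    def test_brute_force_oracle_200_vectors(self, rng):
        for _ in range(200):
            c = int(rng.integers(1, 40))
            w = rng.uniform(0.01, 0.99, c)
            if rng.random() < 0.3:  # inject ties
                w = np.round(w, 1)
            x = float(rng.uniform(0, 0.99))
            mask = select_prune_set(ChannelImportance("L", w, 1), x)
            assert mask.kept_indices.tolist() == _brute_force_prune(w, x)


class TestSelectByThreshold:
    def test_constant_vector_keep_one(self):
        imp = ChannelImportance("L", [0.4] * 6, 1)
        mask = select_by_threshold(imp, ThresholdRule(0.1))
        assert mask.n_kept == 1

    def test_high_importance_keep_one(self):
        imp = ChannelImportance("L", [0.9, 0.9, 0.9], 1)
        # TH = 0.9 + 0 + 0.1 = 1.0 -> all below -> forced keep-one
        mask = select_by_threshold(imp, ThresholdRule(0.1))
        assert mask.kept_indices.tolist() == [0]

    def test_pruned_count_nondecreasing_in_k(self, rng):
        w = rng.uniform(0.2, 0.9, 20)
        imp = ChannelImportance("L", w, 1)
        sizes = [select_by_threshold(imp, ThresholdRule(k)).n_kept
                 for k in (0.1, 0.3, 0.5)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_k_range_enforced(self):
        with pytest.raises(ValueError):
            ThresholdRule(0.05)
        with pytest.raises(ValueError):
            ThresholdRule(0.6)


class TestApplyPruning:
    def test_all_keep_is_noop(self, rng):
        model = build_model(ArchitectureSpec.toy(), seed=0)
        x = rng.standard_normal((3, 3, 64, 64))
        before = model.forward(x, train=False)
        masks = {n: PruneMask(n, np.arange(c))
                 for n, c in model.layer_channels().items()}
        apply_pruning(model, masks)
        after = model.forward(x, train=False)
        np.testing.assert_allclose(after, before, atol=1e-6)

    def test_stem_not_prunable(self):
        model = build_model(ArchitectureSpec.toy(), seed=0)
        with pytest.raises(ValueError, match="not prunable"):
            apply_pruning(model, {"stem": PruneMask("stem", np.arange(4))})

    def test_zero_activation_equivalence_randomized(self, rng):
        # channels with identically-zero activations never change outputs;
        # sizes chosen so the SE bottleneck width is preserved by the slice
        for trial in range(5):
            model = SmallSENet(c1=8, c2=8, reduction=4, seed=int(rng.integers(1e6)))
            dead = sorted(rng.choice(8, size=2, replace=False).tolist())
            for ch in dead:
                model.conv1.weight.value[ch] = 0.0
                model.bn1.gamma.value[ch] = 0.0
                model.bn1.beta.value[ch] = 0.0
                model.bn1.running_mean[ch] = 0.0
                model.bn1.running_var[ch] = 1.0
            x = rng.standard_normal((4, 3, 8, 8))
            before = model.forward(x, train=False)
            kept = np.array([i for i in range(8) if i not in dead])
            pruned = copy.deepcopy(model)
            pruned.prune({"conv1": kept})
            after = pruned.forward(x, train=False)
            np.testing.assert_allclose(after, before, atol=1e-6)

    def test_hybrid_50_percent_masks(self, rng):
        model = build_model(ArchitectureSpec.toy(), seed=0)
        x = rng.standard_normal((4, 3, 64, 64))
        imp = accumulate_importance(model, x)
        masks = plan_masks(model, imp, 0.5)
        w_before, _ = count_params_flops(model, 64)
        apply_pruning(model, masks)
        w_after, _ = count_params_flops(model, 64)
        assert w_after < w_before
        channels = model.layer_channels()
        assert channels == {"3a": 16, "3b": 30, "4a": 32, "4b": 32,
                            "4c": 32, "4d": 33, "4e": 116}
        out = model.forward(x, train=False)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_monotone_compression(self, rng):
        model = build_model(ArchitectureSpec.toy(), seed=1)
        x = rng.standard_normal((3, 3, 64, 64))
        weights = [count_params_flops(model, 64)[0]]
        for _ in range(3):
            imp = accumulate_importance(model, x)
            masks = plan_masks(model, imp, 0.3)
            apply_pruning(model, masks)
            weights.append(count_params_flops(model, 64)[0])
        assert all(b < a for a, b in zip(weights, weights[1:]))

    def test_identity_shortcut_shares_mask(self, rng):
        # widths chosen so 4c and 4d have equal output channels: the shortcut
        # becomes an identity addition and both endpoints must share one mask
        from histocnn.network import ArchitectureSpec, build_model, \
            load_inception_widths

        widths = load_inception_widths()
        widths["4c"] = {"n1": 144, "n3r": 128, "n3": 256, "n5r": 24, "n5": 64,
                        "pool": 64, "total": 528}
        arch = ArchitectureSpec(width_multiplier=0.125, input_side=64,
                                inception_widths=widths)
        model = build_model(arch, seed=0)
        assert model.proj_c is None
        assert ("4c", "4d") in model.residual_coupled_pairs()
        x = rng.standard_normal((2, 3, 64, 64))
        imp = accumulate_importance(model, x)
        masks = plan_masks(model, imp, 0.5)
        np.testing.assert_array_equal(masks["4c"].kept_indices,
                                      masks["4d"].kept_indices)
        apply_pruning(model, masks)
        out = model.forward(x, train=False)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)
        # unequal masks on identity-coupled endpoints are rejected
        model2 = build_model(arch, seed=0)
        bad = plan_masks(model2, accumulate_importance(model2, x), 0.5)
        bad["4c"] = PruneMask("4c", np.arange(1, bad["4c"].n_kept + 1))
        with pytest.raises(ValueError, match="shared mask"):
            apply_pruning(model2, bad)

    def test_mask_validation(self):
        with pytest.raises(ValueError):
            PruneMask("L", [])
        with pytest.raises(ValueError):
            PruneMask("L", [3, 1])
        with pytest.raises(ValueError):
            PruneMask("L", [-1, 2])


class TestPruneRetrainLoop:
    def _toy_data(self, rng, n=12):
        x = rng.standard_normal((n, 3, 8, 8))
        y = np.arange(n) % 2
        return x, y

    def test_half_in_one_loop_32_channels(self, rng):
        model = SmallSENet(c1=32, c2=32, reduction=16, seed=0)
        x, y = self._toy_data(rng)
        cfg = TrainConfig.desk(iterations=2, batch_size=4, initial_lr=1e-3)
        model, reports = prune_retrain_loop(model, x, y, PruneSchedule(0.5, 1), cfg)
        assert model.layer_channels() == {"conv1": 16, "conv2": 16}
        assert reports[0].channels_before == {"conv1": 32, "conv2": 32}

    def test_two_loop_75_percent_64_channels(self, rng):
        model = SmallSENet(c1=64, c2=64, reduction=16, seed=0)
        x, y = self._toy_data(rng)
        cfg = TrainConfig.desk(iterations=1, batch_size=4, initial_lr=1e-3)
        model, reports = prune_retrain_loop(model, x, y, PruneSchedule(0.75, 2), cfg)
        # X = 0.5 per loop: 64 -> 32 -> 16
        assert reports[0].channels_after["conv1"] == 32
        assert reports[1].channels_after["conv1"] == 16

    def test_zero_target_leaves_channels(self, rng):
        model = SmallSENet(c1=8, c2=8, seed=0)
        x, y = self._toy_data(rng)
        cfg = TrainConfig.desk(iterations=1, batch_size=4, initial_lr=1e-4)
        model, reports = prune_retrain_loop(model, x, y, PruneSchedule(0.0, 3), cfg)
        assert len(reports) == 3
        assert model.layer_channels() == {"conv1": 8, "conv2": 8}

    def test_retrain_lr_is_reduced(self, rng, monkeypatch):
        seen = []
        import histocnn.pruning as pruning_mod

        def fake_train(model, x, y, cfg):
            seen.append(cfg.initial_lr)
            return [0.1]

        monkeypatch.setattr("histocnn.training.train_branch", fake_train)
        model = SmallSENet(c1=8, c2=8, seed=0)
        x, y = self._toy_data(rng)
        cfg = TrainConfig.desk(iterations=5, initial_lr=0.02, batch_size=4)
        pruning_mod.prune_retrain_loop(model, x, y, PruneSchedule(0.5, 1), cfg)
        assert seen == [pytest.approx(0.002)]


def test_channel_importance_validation():
    with pytest.raises(ValueError):
        ChannelImportance("L", [0.5], 0)
    with pytest.raises(ValueError):
        ChannelImportance("L", [1.5], 1)
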