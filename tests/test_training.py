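import numpy as np
import pytest

from perinet.bounding import BoundedSample
from perinet.nets import Network, build
from perinet.training import (
    TrainConfig,
    augment,
    balance_training,
    build_folds,
    train_network,
    train_one_fold,
    grid_search,
)


def make_samples(labels, option="2ds", seed=0, signal=0.0):
    """Small 2D samples; optional class-dependent mean shift ``signal``."""
    rng = np.random.default_rng(seed)
    samples = []
    for i, lab in enumerate(labels):
        data = rng.random((4, 64, 64)).astype(np.float32) * 0.5
        if lab == 1:
            data = np.clip(data + signal, 0, 1)
        samples.append(BoundedSample(f"P{i:03d}", "all", option, data, int(lab)))
    return samples


class TestFoldPlan:
    def test_27_positives_split_as_pigeonhole(self):
        ids = [f"P{i}" for i in range(155)]
        labels = [1] * 27 + [0] * 128
        plan = build_folds(ids, labels, k=10, seed=0)
        pos_per_fold = sorted(
            sum(1 for p in fold if int(p[1:]) < 27) for fold in plan.folds
        )
        assert pos_per_fold == [2, 2, 2, 3, 3, 3, 3, 3, 3, 3]

    def test_even_split(self):
        plan = build_folds([f"P{i}" for i in range(20)], [i % 2 for i in range(20)], k=10, seed=1)
        assert all(len(f) == 2 for f in plan.folds)

    def test_deterministic_under_seed(self):
        ids = [f"P{i}" for i in range(30)]
        labels = [i % 3 == 0 for i in range(30)]
        a = build_folds(ids, labels, seed=7)
        b = build_folds(ids, labels, seed=7)
        assert a.folds == b.folds

    def test_fewer_patients_than_folds_rejected(self):
        with pytest.raises(ValueError, match="at least k"):
            build_folds(["a", "b"], [0, 1], k=10)

    def test_each_patient_once_in_test_and_validation(self):
        ids = [f"P{i}" for i in range(34)]
        labels = [i % 5 == 0 for i in range(34)]
        plan = build_folds(ids, labels, k=10, seed=3)
        test_seen, val_seen = [], []
        for it in range(plan.k):
            train, val, test = plan.iteration(it)
            assert not (set(train) & (set(val) | set(test)))  # leakage check
            test_seen += test
            val_seen += val
        assert sorted(test_seen) == sorted(ids)
        assert sorted(val_seen) == sorted(ids)

    def test_negative_patients_excluded_twice_across_iterations(self):
        ids = [f"P{i}" for i in range(40)]
        labels = [1 if i < 8 else 0 for i in range(40)]
        n_neg = 32
        plan = build_folds(ids, labels, k=10, seed=0)
        total_train_neg = sum(
            sum(1 for p in plan.iteration(it)[0] if int(p[1:]) >= 8)
            for it in range(plan.k)
        )
        assert total_train_neg == plan.k * n_neg - 2 * n_neg

    def test_bilateral_lesions_share_a_fold(self):
        ids = [f"L{i}" for i in range(20)] + ["L20a", "L20b"]
        labels = [i % 4 == 0 for i in range(20)] + [1, 0]
        groups = {"L20a": "subject20", "L20b": "subject20"}
        plan = build_folds(ids, labels, k=10, seed=2, groups=groups)
        fold_of = {p: i for i, fold in enumerate(plan.folds) for p in fold}
        assert fold_of["L20a"] == fold_of["L20b"]


class TestBalancing:
    def test_table_counts_23_101(self):
        samples = make_samples([1] * 23 + [0] * 101)
        balanced = balance_training(samples, seed=0)
        labels = [s.label for s in balanced]
        assert labels.count(1) == 101 and labels.count(0) == 101
        assert len(balanced) == 202

    def test_already_balanced_unchanged(self):
        samples = make_samples([1, 0, 1, 0])
        assert balance_training(samples, seed=0) == samples

    def test_single_minority_sample_forced_duplicates(self):
        samples = make_samples([1] + [0] * 5)
        balanced = balance_training(samples, seed=0)
        minority = [s for s in balanced if s.label == 1]
        assert len(minority) == 5
        assert all(s is samples[0] for s in minority)

    def test_majority_untouched_nothing_dropped(self):
        samples = make_samples([1] * 3 + [0] * 9, seed=4)
        balanced = balance_training(samples, seed=1)
        assert balanced[: len(samples)] == samples

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            balance_training(make_samples([0, 0, 0]))


class _ScriptedRng:
    """Deterministic stand-in driving augment through a fixed path."""

    def __init__(self, uniforms, ints=()):
        self._u = list(uniforms)
        self._i = list(ints)

    def random(self):
        return self._u.pop(0)

    def integers(self, lo, hi):
        return self._i.pop(0)


class TestAugmentation:
    def test_no_transform_is_identity(self):
        data = np.random.default_rng(0).random((4, 8, 8, 6)).astype(np.float32)
        out = augment(data, _ScriptedRng([0.9, 0.9, 0.9]))
        np.testing.assert_array_equal(out, data)

    def test_180_rotation_twice_is_identity(self):
        data = np.random.default_rng(1).random((4, 8, 8)).astype(np.float32)
        once = augment(data, _ScriptedRng([0.9, 0.9, 0.1], [2]))
        twice = augment(once, _ScriptedRng([0.9, 0.9, 0.1], [2]))
        np.testing.assert_array_equal(twice, data)

    @pytest.mark.parametrize("seed", range(4))
    def test_any_composition_preserves_voxel_multiset_and_shape(self, seed):
        rng = np.random.default_rng(seed)
        data = np.random.default_rng(10 + seed).random((4, 6, 6, 5)).astype(np.float32)
        out = augment(data, rng)
        assert out.shape == data.shape
        np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(data.ravel()))

    def test_channels_transformed_identically(self):
        base = np.random.default_rng(2).random((6, 6)).astype(np.float32)
        data = np.stack([base, base + 1, base + 2, base + 3])
        out = augment(data, np.random.default_rng(5))
        np.testing.assert_allclose(out[1] - out[0], 1.0, atol=1e-6)


class TestTrainingLoop:
    def test_training_is_deterministic_under_seed(self):
        samples = make_samples([1] * 4 + [0] * 4, signal=0.3)
        cfg = TrainConfig(max_epochs=2, batch_size=4, learning_rate=1e-3,
                          width_scale=0.125, seed=9)
        traces = []
        for _ in range(2):
            net = Network(build("2DS-NET", width_scale=0.125), seed=9)
            traces.append(train_network(net, samples, samples[:4], cfg))
        assert traces[0].val_loss == traces[1].val_loss

    def test_learns_planted_mean_shift(self):
        # strong class-dependent signal: validation loss must beat chance
        samples = make_samples([1] * 8 + [0] * 8, signal=0.4, seed=2)
        cfg = TrainConfig(max_epochs=12, batch_size=8, learning_rate=1e-3,
                          width_scale=0.125, augment_prob=0.0, seed=1)
        net = Network(build("2DS-NET", width_scale=0.125), seed=1)
        trace = train_network(net, samples, samples, cfg)
        assert trace.best_val_loss < 0.5  # well below ln 2

    def test_empty_training_set_rejected(self):
        net = Network(build("2DS-NET", width_scale=0.125), seed=0)
        with pytest.raises(ValueError, match="empty training set"):
            train_network(net, [], [], TrainConfig(max_epochs=1))

    def test_train_one_fold_respects_fold_plan(self):
        labels = [1] * 4 + [0] * 8
        samples = make_samples(labels, signal=0.3)
        plan = build_folds(
            [s.patient_id for s in samples], labels, k=4, seed=0
        )
        cfg = TrainConfig(max_epochs=1, batch_size=4, learning_rate=1e-3,
                          width_scale=0.125, seed=0)
        net, trace = train_one_fold(samples, plan, 0, "2ds", cfg)
        assert len(trace.val_loss) == 1
        assert np.isfinite(trace.best_val_loss)


class TestGridSearch:
    def _tiny(self):
        labels = [1] * 4 + [0] * 8
        samples = make_samples(labels, signal=0.4)
        plan = build_folds([s.patient_id for s in samples], labels, k=4, seed=0)
        return samples, plan

    def test_single_point_grid_returns_it(self):
        samples, plan = self._tiny()
        cfg = TrainConfig(max_epochs=1, batch_size=4, learning_rate=1e-4,
                          width_scale=0.125, seed=0)
        assert grid_search(samples, plan, "2ds", [cfg], iterations=[0]) is cfg

    def test_paper_scale_config_is_in_search_space(self):
        # batch in (8, 64), lr in (1e-7, 1e-3), weight decay in (0, 1e-4)
        grid = [
            TrainConfig(batch_size=b, learning_rate=lr, weight_decay=wd)
            for b in (8, 16, 32, 64)
            for lr in (1e-7, 1e-6, 1e-5, 1e-4, 1e-3)
            for wd in (0.0, 1e-4)
        ]
        assert any(
            c.batch_size == 16 and c.learning_rate == 1e-6 and c.weight_decay == 1e-4
            for c in grid
        )

    def test_empty_grid_rejected(self):
        samples, plan = self._tiny()
        with pytest.raises(ValueError, match="empty"):
            grid_search(samples, plan, "2ds", [])
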