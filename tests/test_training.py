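"""Loss, schedule, reproducibility and cross-validation splitting."""

import numpy as np
import pytest

from hnseg.model import ModelConfig, build_model
from hnseg.nn import Tensor
from hnseg.training import (
    TrainConfig,
    fine_tune,
    learning_rate_at,
    make_folds,
    soft_dice_loss,
    train,
)

TINY_MODEL = dict(input_size=16, depth=2, base_channels=2)


def ellipse_dataset(n, rng, size=16):
    """Trivially separable bright-ellipse-on-dark slices."""
    data = []
    for _ in range(n):
        rr, cc = np.ogrid[:size, :size]
        cy, cx = rng.uniform(size * 0.3, size * 0.7, 2)
        a, b = rng.uniform(2.5, 4.5, 2)
        mask = (((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1)
        img = np.clip(0.25 + 0.5 * mask +
                      rng.normal(0, 0.03, (size, size)), 0, 1)
        data.append((img, mask.astype(np.uint8)))
    return data


class TestSoftDiceLoss:
    def test_perfect_prediction_near_zero(self, rng):
        t = (rng.random((2, 1, 8, 8)) > 0.6).astype(float)
        assert soft_dice_loss(t.copy(), t) == pytest.approx(0.0, abs=1e-6)

    def test_complementary_masks_near_one(self):
        t = np.zeros((1, 1, 4, 4))
        t[..., :2] = 1
        p = 1.0 - t
        assert soft_dice_loss(p, t) == pytest.approx(1.0, abs=1e-6)

    def test_half_covered_target(self):
        # |target| = 100, prediction covers 50 of it and nothing else
        t = np.zeros((1, 1, 10, 20))
        t[..., :10] = 1.0
        p = np.zeros_like(t)
        p[..., :5] = 1.0
        assert soft_dice_loss(p, t) == pytest.approx(1 / 3, abs=1e-6)

    def test_tensor_and_array_paths_agree(self, rng):
        p = rng.random((2, 1, 6, 6))
        t = (rng.random((2, 1, 6, 6)) > 0.5).astype(float)
        assert float(soft_dice_loss(Tensor(p), t).data) == \
            pytest.approx(soft_dice_loss(p, t))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))


class TestSchedule:
    def test_decay_arithmetic(self):
        cfg = TrainConfig(learning_rate=0.01, lr_decay_factor=0.8,
                          lr_decay_every=10, epochs=21)
        assert learning_rate_at(0, cfg) == pytest.approx(0.01)
        assert learning_rate_at(9, cfg) == pytest.approx(0.01)
        assert learning_rate_at(10, cfg) == pytest.approx(0.008)
        assert learning_rate_at(20, cfg) == pytest.approx(0.01 * 0.8 ** 2)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(beta1=1.2)
        with pytest.raises(ValueError):
            TrainConfig(lr_decay_factor=0.0)


class TestTrain:
    def test_loss_halves_on_separable_data(self, rng):
        data = ellipse_dataset(20, rng)
        model = build_model(ModelConfig(**TINY_MODEL, seed=0))
        _, hist = train(model, data, TrainConfig(epochs=10, seed=0,
                                                 batch_size=5))
        assert hist.losses[-1] <= 0.5 * hist.losses[0]
        assert all(np.isfinite(hist.losses))
        assert len(hist.losses) == 10

    def test_identical_seeds_identical_histories(self, rng):
        data = ellipse_dataset(6, rng)
        hists = []
        for _ in range(2):
            model = build_model(ModelConfig(**TINY_MODEL, seed=1))
            _, h = train(model, data, TrainConfig(epochs=2, seed=1,
                                                  batch_size=3))
            hists.append(h.losses)
        assert hists[0] == hists[1]

    def test_empty_dataset_rejected(self):
        model = build_model(ModelConfig(**TINY_MODEL, seed=0))
        with pytest.raises(ValueError):
            train(model, [], TrainConfig(epochs=1))


class TestFineTune:
    def test_zero_epochs_leaves_weights_unchanged(self, rng):
        data = ellipse_dataset(4, rng)
        model = build_model(ModelConfig(**TINY_MODEL, seed=0))
        train(model, data, TrainConfig(epochs=1, seed=0))
        before = model.state_dict()
        _, hist = fine_tune(model, data, [], TrainConfig(epochs=0, seed=0))
        after = model.state_dict()
        assert hist.losses == []
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_continues_rather_than_reinitializes(self, rng):
        data = ellipse_dataset(4, rng)
        model = build_model(ModelConfig(**TINY_MODEL, seed=0))
        train(model, data, TrainConfig(epochs=2, seed=0))
        trained = {k: v.copy() for k, v in model.state_dict().items()}
        fine_tune(model, data, ellipse_dataset(2, rng),
                  TrainConfig(epochs=1, seed=0))
        fresh = build_model(ModelConfig(**TINY_MODEL, seed=0)).state_dict()
        moved_from_fresh = any(not np.allclose(model.state_dict()[k],
                                               fresh[k]) for k in fresh)
        assert moved_from_fresh
        # and it started from the trained weights, not from scratch:
        # one epoch of fine-tuning stays closer to trained than to fresh
        key = next(k for k in trained if trained[k].ndim > 1)
        d_trained = np.abs(model.state_dict()[key] - trained[key]).mean()
        d_fresh = np.abs(model.state_dict()[key] - fresh[key]).mean()
        assert d_trained < d_fresh

    def test_unlabeled_added_samples_rejected(self, rng):
        model = build_model(ModelConfig(**TINY_MODEL, seed=0))
        with pytest.raises(ValueError):
            fine_tune(model, ellipse_dataset(2, rng),
                      [(np.zeros((16, 16)), None)], TrainConfig(epochs=1))


class TestCrossValidate:
    def test_case_level_folds_and_pooled_summary(self, tiny_spec):
        from hnseg.phantom import generate_phantom_pool, pool_to_cases
        from hnseg.training import crossvalidate
        cases = pool_to_cases(generate_phantom_pool(tiny_spec, 4, seed=2))
        cfg = ModelConfig(input_size=32, depth=2, base_channels=2, seed=0)
        folds, summary = crossvalidate(
            cases, cfg, TrainConfig(epochs=1, seed=0, batch_size=4), k=2)
        assert len(folds) == 2
        val_ids = [cid for f in folds for cid in f["val_cases"]]
        assert sorted(val_ids) == sorted(cases.keys())
        assert summary["n_cases"] == 4
        assert 0.0 <= summary["mean_dice"] <= 1.0


class TestFolds:
    def test_partition_properties(self):
        ids = [f"c{i}" for i in range(10)]
        folds = make_folds(ids, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(f) == 2 for f in folds)
        flat = [c for f in folds for c in f]
        assert sorted(flat) == sorted(ids)  # disjoint cover

    def test_same_seed_same_assignment(self):
        ids = [f"c{i}" for i in range(7)]
        assert make_folds(ids, 3, seed=5) == make_folds(ids, 3, seed=5)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=5, seed=0)
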