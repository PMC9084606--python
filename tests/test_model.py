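import hashlib

import numpy as np
import pytest

from planereg import nn
from planereg.model import (
    ModelSpec,
    TrainConfig,
    build_model,
    make_sampler,
    oversample_weights,
    parameter_count,
    predict,
    reduced_model_spec,
    save_model,
    load_model,
    train,
    train_step,
)
from planereg.phantom import PhantomSpec, generate_dataset

REGIONS = ("calcaneus", "ankle", "knee", "wrist")
SMALL_PHANTOM = PhantomSpec(shape=(32, 32, 32), spacing=(5.0,) * 3)


def small_spec(**kw):
    return reduced_model_spec(**kw)


def param_hashes(module):
    return [hashlib.sha256(p.data.tobytes()).hexdigest() for p in module.parameters()]


class TestBuildModel:
    def test_baseline_output_width(self):
        model = build_model(small_spec(codec="six_d_xy"))
        x = np.zeros((1, 1, 32, 32, 32), dtype=np.float32)
        model.train(False)
        assert model.forward(x).shape == (1, 27)

    def test_quaternion_output_width(self):
        model = build_model(small_spec(codec="quaternion"))
        model.train(False)
        x = np.zeros((1, 1, 32, 32, 32), dtype=np.float32)
        assert model.forward(x).shape == (1, 21)

    def test_full_size_flatten_is_10240(self):
        # full architecture: the flattened trunk feature dimension
        model = build_model(ModelSpec())
        assert model.n_features == 10240

    def test_multihead_shares_trunk(self):
        model = build_model(small_spec(mode="multi_head", regions=REGIONS))
        assert set(model.heads) == set(REGIONS)
        trunk_params = sum(p.data.size for p in model.trunk.parameters())
        assert trunk_params > 0

    def test_multihead_smaller_than_four_baselines(self):
        multi = build_model(small_spec(mode="multi_head", regions=REGIONS))
        single = build_model(small_spec(mode="baseline"))
        assert parameter_count(multi) < 4 * parameter_count(single)

    def test_unknown_region_head_rejected(self):
        model = build_model(small_spec(mode="multi_head", regions=("ankle",)))
        with pytest.raises(ValueError):
            model.head_for("knee")


class TestLoss:
    def test_zero_for_identical(self):
        x = np.ones((2, 27), dtype=np.float32)
        loss, grad = nn.mse_loss(x, x.copy())
        assert loss == 0.0 and np.all(grad == 0)

    def test_constant_offset(self):
        x = np.zeros((3, 9), dtype=np.float32)
        loss, _ = nn.mse_loss(x + 0.1, x)
        assert np.isclose(loss, 0.01, atol=1e-9)

    def test_matches_brute_force(self, rng):
        a = rng.normal(size=(4, 27)).astype(np.float32)
        b = rng.normal(size=(4, 27)).astype(np.float32)
        loss, _ = nn.mse_loss(a, b)
        brute = sum(
            (float(a[i, j]) - float(b[i, j])) ** 2 for i in range(4) for j in range(27)
        ) / (4 * 27)
        assert np.isclose(loss, brute, rtol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nn.mse_loss(np.zeros((2, 27)), np.zeros((2, 21)))


class TestHeadIsolation:
    def test_single_region_batch_leaves_other_heads_untouched(self, rng):
        model = build_model(small_spec(mode="multi_head", regions=REGIONS, seed=0))
        opt = nn.SGD(model.parameters(), lr=0.01, momentum=0.9)
        before = {r: param_hashes(model.heads[r]) for r in REGIONS}
        trunk_before = param_hashes(model.trunk)
        x = rng.normal(size=(3, 1, 32, 32, 32)).astype(np.float32)
        y = rng.normal(size=(3, 27)).astype(np.float32)
        train_step(model, opt, x, y, regions=["ankle"] * 3)
        after = {r: param_hashes(model.heads[r]) for r in REGIONS}
        assert after["ankle"] != before["ankle"]
        for r in ("calcaneus", "knee", "wrist"):
            assert after[r] == before[r]
        assert param_hashes(model.trunk) != trunk_before

    def test_mixed_batch_trunk_gets_all_gradients(self, rng):
        # trunk gradient of a mixed batch equals the weighted sum of the
        # per-region sub-batch gradients (per-sample accumulation oracle)
        model = build_model(small_spec(mode="multi_head", regions=("ankle", "knee"), seed=1))
        x = rng.normal(size=(4, 1, 32, 32, 32)).astype(np.float32)
        y = rng.normal(size=(4, 27)).astype(np.float32)
        regions = np.array(["ankle", "ankle", "knee", "knee"])
        model.train(True)

        def trunk_grad_for(sel, frac):
            model.zero_grad()
            pred = model.forward(x[sel], regions[sel][0])
            _, grad = nn.mse_loss(pred, y[sel])
            model.backward_from(grad * frac, regions[sel][0])
            return [p.grad.copy() for p in model.trunk.parameters()]

        g_ankle = trunk_grad_for(np.array([0, 1]), 0.5)
        g_knee = trunk_grad_for(np.array([2, 3]), 0.5)

        model.zero_grad()
        opt = nn.SGD([], lr=0.0)
        total = 4 * 27
        for region in ("ankle", "knee"):
            sel = np.flatnonzero(regions == region)
            pred = model.forward(x[sel], region)
            _, grad = nn.mse_loss(pred, y[sel])
            model.backward_from(grad * (pred.size / total), region)
        mixed = [p.grad.copy() for p in model.trunk.parameters()]
        for m, a, k in zip(mixed, g_ankle, g_knee):
            assert np.allclose(m, a + k, atol=1e-5)

    def test_zero_learning_rate_changes_nothing(self, rng):
        model = build_model(small_spec(mode="multi_head", regions=REGIONS, seed=2))
        opt = nn.SGD(model.parameters(), lr=0.0, momentum=0.9)
        before = param_hashes(model)
        x = rng.normal(size=(2, 1, 32, 32, 32)).astype(np.float32)
        y = rng.normal(size=(2, 27)).astype(np.float32)
        train_step(model, opt, x, y, regions=["ankle", "knee"])
        assert param_hashes(model) == before


class TestSampler:
    def test_balanced_input_stays_balanced(self):
        w = oversample_weights(["a"] * 100 + ["b"] * 100)
        assert np.allclose(w.sum(), 1.0)
        assert np.allclose(w[:100].sum(), 0.5)

    def test_imbalanced_counts_equalized(self, rng):
        regions = ["a"] * 300 + ["b"] * 100
        sampler = make_sampler(regions, rng)
        draws = [regions[next(sampler)] for _ in range(10_000)]
        freq_a = draws.count("a") / len(draws)
        assert abs(freq_a - 0.5) <= 0.02

    def test_single_region(self, rng):
        sampler = make_sampler(["a"] * 5, rng)
        assert all(0 <= next(sampler) < 5 for _ in range(20))

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            oversample_weights([])


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_dataset(
        8, spec=SMALL_PHANTOM, max_angle_deg=20, max_translation_mm=5, seed=7
    )


class TestTrainLoop:
    def test_zero_lr_one_epoch_keeps_weights(self, tiny_dataset):
        model = build_model(small_spec(seed=3))
        before = param_hashes(model)
        cfg = TrainConfig(
            epochs=1, learning_rate=0.0, momentum=0.0, batch_size=4, seed=0, augment=None
        )
        train(model, tiny_dataset, cfg)
        assert param_hashes(model) == before

    def test_fixed_seed_reproducible_first_epoch(self, tiny_dataset):
        losses = []
        for _ in range(2):
            model = build_model(small_spec(seed=3))
            cfg = TrainConfig(
                epochs=1, learning_rate=0.001, momentum=0.9, batch_size=4, seed=11, augment=None
            )
            log = train(model, tiny_dataset, cfg)
            losses.append(log[0]["loss"])
        assert losses[0] == losses[1]

    def test_loss_decreases_over_short_training(self, tiny_dataset):
        model = build_model(small_spec(seed=3))
        cfg = TrainConfig(
            epochs=10, learning_rate=0.01, momentum=0.9, batch_size=4, seed=0, augment=None
        )
        log = train(model, tiny_dataset, cfg)
        assert log[-1]["loss"] < 0.5 * log[0]["loss"]

    def test_lr_decay_schedule_applied(self, tiny_dataset):
        model = build_model(small_spec(seed=3))
        cfg = TrainConfig(
            epochs=4, learning_rate=0.008, lr_decay=0.5, lr_decay_step=2,
            momentum=0.0, batch_size=8, seed=0, augment=None,
        )
        log = train(model, tiny_dataset, cfg)
        assert np.isclose(log[1]["lr"], 0.008)
        assert np.isclose(log[2]["lr"], 0.004)


class TestPredict:
    def test_untrained_model_yields_valid_triplet(self, tiny_dataset=None):
        samples = generate_dataset(5, spec=SMALL_PHANTOM, seed=1)
        model = build_model(small_spec(seed=0))
        t = predict(model, samples[0].volume, samples[0].geometry, "ankle")
        assert t.region == "ankle"
        for p in t.planes:
            assert np.isclose(np.linalg.norm(p.e_u), 1.0, atol=1e-9)
            assert abs(p.e_u @ p.e_v) < 1e-9

    def test_inference_deterministic(self):
        samples = generate_dataset(5, spec=SMALL_PHANTOM, seed=1)
        model = build_model(small_spec(seed=0))
        t1 = predict(model, samples[0].volume, samples[0].geometry, "ankle")
        t2 = predict(model, samples[0].volume, samples[0].geometry, "ankle")
        for a, b in zip(t1.planes, t2.planes):
            assert np.array_equal(a.center, b.center)
            assert np.array_equal(a.e_u, b.e_u)

    def test_save_load_round_trip(self, tmp_path):
        samples = generate_dataset(5, spec=SMALL_PHANTOM, seed=1)
        model = build_model(small_spec(mode="multi_head", regions=("ankle", "knee"), seed=4))
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        t1 = predict(model, samples[0].volume, samples[0].geometry, "ankle")
        t2 = predict(back, samples[0].volume, samples[0].geometry, "ankle")
        for a, b in zip(t1.planes, t2.planes):
            assert np.allclose(a.center, b.center, atol=1e-6)
            assert np.allclose(a.e_u, b.e_u, atol=1e-9)


class TestOverfitOneBatch:
    def test_loss_drops_on_single_batch(self, rng):
        """Optimization sanity: repeated steps on one batch drive the loss down."""
        samples = generate_dataset(6, spec=SMALL_PHANTOM, max_angle_deg=25, seed=9)
        from planereg.preprocessing import intensity_normalize
        from planereg.rotations import build_parameter_vector, get_codec

        codec = get_codec("six_d_xy")
        x = np.stack(
            [intensity_normalize(s.volume)[None] for s in samples]
        ).astype(np.float32)
        y = np.stack(
            [build_parameter_vector(s.triplet, codec, s.geometry) for s in samples]
        ).astype(np.float32)
        model = build_model(small_spec(seed=0))
        opt = nn.SGD(model.parameters(), lr=0.01, momentum=0.9)
        first = None
        for step in range(200):
            opt.zero_grad()
            pred = model.forward(x)
            loss, grad = nn.mse_loss(pred, y)
            if first is None:
                first = loss
            model.backward_from(grad)
            opt.step()
        assert loss < 0.01 * first
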