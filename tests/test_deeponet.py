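import numpy as np
import pytest

from platonet.dataset import NormalizationStats, OperatorDataset, random_split
from platonet.deeponet import (
    SurrogateModel,
    SurrogateSpec,
    TrainingPlan,
    forward,
    load_checkpoint,
    predict_shape,
    save_checkpoint,
    train,
)


def toy_dataset(n=4000, seed=0, target_fn=None):
    rng = np.random.default_rng(seed)
    branch = rng.uniform(0, 1, (n, 2))
    trunk = rng.uniform(0, 1, (n, 4))
    if target_fn is None:
        A = rng.normal(size=(2, 4, 3)) * 0.3
        target = np.einsum("ni,ijk,nj->nk", branch, A, trunk)
    else:
        target = target_fn(branch, trunk)
    return OperatorDataset(
        branch=branch, trunk=trunk, target=target,
        traj_index=np.zeros(n, np.int32), snap_index=np.zeros(n, np.int32),
        vertex_index=np.zeros(n, np.int32),
        K_values=np.array([1.0]), Ca_values=np.array([1.0]), diameter=1.0,
    )


def identity_stats():
    return NormalizationStats(
        branch_min=np.zeros(2), branch_max=np.ones(2),
        trunk_min=np.zeros(4), trunk_max=np.ones(4),
    )


class TestArchitecture:
    def test_parameter_count_closed_form(self):
        spec = SurrogateSpec()
        # branch 2->32->16->32, trunk 4->32->32->16->32, readout 32->3
        expected = (2 * 32 + 32) + (32 * 16 + 16) + (16 * 32 + 32)
        expected += (4 * 32 + 32) + (32 * 32 + 32) + (32 * 16 + 16) + (16 * 32 + 32)
        expected += 32 * 3 + 3
        assert spec.parameter_count() == expected
        model = SurrogateModel.initialize(spec)
        assert model.parameter_count() == expected

    def test_latent_width_shared(self):
        spec = SurrogateSpec()
        assert spec.branch_layers()[-1][1] == spec.trunk_layers()[-1][1] == 32

    def test_zero_weights_output_is_bias(self):
        model = SurrogateModel.initialize(SurrogateSpec(init_seed=1))
        for p in model.parameters():
            p[...] = 0.0
        model.readout_b[...] = np.array([0.5, -0.25, 1.0], dtype=np.float32)
        out = forward(model, np.random.rand(7, 2), np.random.rand(7, 4))
        assert np.allclose(out, [0.5, -0.25, 1.0])

    def test_forward_matches_closed_form_in_linear_regime(self):
        # non-negative weights/biases keep every pre-activation non-negative
        # on [0, 1]^d inputs, so each ReLU is the identity and the network
        # reduces to an affine chain computable by hand
        rng = np.random.default_rng(3)
        model = SurrogateModel.initialize(SurrogateSpec(init_seed=2))
        for W, b in model.branch + model.trunk:
            W[...] = np.abs(W)
            b[...] = np.abs(b)

        def affine(layers, x):
            h = x.astype(np.float64)
            for W, b in layers:
                h = h @ W.astype(np.float64) + b.astype(np.float64)
            return h

        bx = rng.uniform(0, 1, (11, 2)).astype(np.float32)
        tx = rng.uniform(0, 1, (11, 4)).astype(np.float32)
        b_lat = affine(model.branch, bx)
        t_lat = affine(model.trunk, tx)
        expected = (b_lat * t_lat) @ model.readout_W.astype(np.float64) \
            + model.readout_b.astype(np.float64)
        got = forward(model, bx, tx)
        assert np.allclose(got, expected, rtol=1e-4, atol=1e-3)

    def test_forward_deterministic(self):
        model = SurrogateModel.initialize(SurrogateSpec(init_seed=4))
        bx = np.random.default_rng(0).random((5, 2))
        tx = np.random.default_rng(1).random((5, 4))
        assert np.array_equal(forward(model, bx, tx), forward(model, bx, tx))

    def test_nonfinite_inputs_rejected(self):
        model = SurrogateModel.initialize(SurrogateSpec())
        bad = np.full((1, 2), np.nan)
        with pytest.raises(ValueError):
            forward(model, bad, np.zeros((1, 4)))


class TestTraining:
    def test_constant_target_converges(self):
        const = np.array([0.3, -0.1, 0.2])
        ds = toy_dataset(
            n=2000, target_fn=lambda b, t: np.tile(const, (len(b), 1))
        )
        tr, va, _ = random_split(ds, 0.9, seed=0)
        model, hist = train(
            SurrogateSpec(init_seed=0), TrainingPlan(epochs=100), tr, va
        )
        assert hist["train_mse"].iloc[-1] < 1e-6

    def test_learns_bilinear_operator(self):
        ds = toy_dataset(n=20000, seed=1)
        tr, va, _ = random_split(ds, 0.9, seed=1)
        model, hist = train(
            SurrogateSpec(init_seed=1), TrainingPlan(epochs=100), tr, va
        )
        rel = np.sqrt(hist["val_mse"].min() / np.mean(ds.target**2))
        assert rel < 0.05

    def test_learning_rate_never_increases_never_below_floor(self):
        ds = toy_dataset(n=3000)
        tr, va, _ = random_split(ds, 0.9, seed=2)
        plan = TrainingPlan(epochs=40, plateau_patience=2, lr_floor=1e-7)
        _, hist = train(SurrogateSpec(init_seed=2), plan, tr, va)
        lr = hist["lr"].to_numpy()
        assert np.all(np.diff(lr) <= 0)
        assert lr.min() >= 1e-7

    def test_more_epochs_never_worse(self):
        ds = toy_dataset(n=3000)
        tr, va, _ = random_split(ds, 0.9, seed=3)
        spec = SurrogateSpec(init_seed=5)
        _, h_short = train(spec, TrainingPlan(epochs=10, shuffle_seed=9), tr, va)
        _, h_long = train(spec, TrainingPlan(epochs=20, shuffle_seed=9), tr, va)
        assert h_long["val_mse"].min() <= h_short["val_mse"].min() + 1e-12

    def test_history_schema(self):
        ds = toy_dataset(n=1000)
        tr, va, _ = random_split(ds, 0.9, seed=4)
        _, hist = train(SurrogateSpec(), TrainingPlan(epochs=3), tr, va)
        assert list(hist.columns) == ["epoch", "train_mse", "val_mse", "val_mae", "lr"]
        assert len(hist) == 4  # epoch 0 (untrained) + 3 epochs

    def test_empty_partition_rejected(self):
        ds = toy_dataset(n=100)
        with pytest.raises(ValueError):
            train(SurrogateSpec(), TrainingPlan(epochs=1), ds.subset(np.array([], int)), ds)


class TestPredictShape:
    def _trained_model(self):
        ds = toy_dataset(n=5000, seed=6)
        tr, va, _ = random_split(ds, 0.9, seed=6)
        model, _ = train(SurrogateSpec(init_seed=6), TrainingPlan(epochs=5), tr, va)
        return model

    def test_branch_factorization(self):
        # shared branch evaluation equals independent full evaluations
        model = self._trained_model()
        rng = np.random.default_rng(7)
        x0 = rng.uniform(0.2, 0.8, (50, 3))
        pred = predict_shape(model, x0, 0.5, sigma=0.5, K=0.5)
        bx = model.stats.normalize_branch(np.tile([[0.5, 0.5]], (50, 1)))
        tx = model.stats.normalize_trunk(np.column_stack([x0, np.full(50, 0.5)]))
        single = x0 + model.diameter * forward(model, bx, tx).astype(float)
        assert np.allclose(pred, single, rtol=0, atol=1e-12)

    def test_time_extrapolation_warns(self):
        model = self._trained_model()
        with pytest.warns(UserWarning, match="outside the trained range"):
            predict_shape(model, np.zeros((2, 3)), 1.5, 0.5, 0.5)


class TestCheckpoint:
    def test_round_trip_bit_identical(self, tmp_path):
        ds = toy_dataset(n=2000, seed=8)
        tr, va, _ = random_split(ds, 0.9, seed=8)
        model, _ = train(SurrogateSpec(init_seed=8), TrainingPlan(epochs=3), tr, va)
        path = save_checkpoint(model, tmp_path / "ck.npz")
        again = load_checkpoint(path)
        bx = np.random.default_rng(9).random((13, 2))
        tx = np.random.default_rng(10).random((13, 4))
        assert np.array_equal(forward(model, bx, tx), forward(again, bx, tx))
        assert again.spec == model.spec
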