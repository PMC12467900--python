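"""Branch/trunk operator network (DeepONet) in plain NumPy.

The branch net encodes the flow/material parameters (sigma, K) and the
trunk net the query coordinates (x0, t_hat); both end in a shared
32-dimensional latent layer.  Their latent vectors are combined by an
elementwise product and mapped to the three Cartesian displacement
components by a final linear layer W:

    dx(t) = W (b(sigma, K) * tau(x0, t_hat)) + w0.

A strict scalar inner product followed by a 1 -> 3 map would force all
predicted displacements at fixed (sigma, K) onto a single direction, so the
elementwise-product readout -- the standard multi-output generalization --
is used.

Hidden layers use ReLU; latent outputs and the readout are linear.
Training minimizes the mean squared error with Adam, a reduce-on-plateau
learning-rate schedule (initial 1e-3, halved after a patience of stagnant
validation epochs, floored at 1e-7), and tracks validation MAE to detect
overfitting.  The implementation is self-contained: forward, backward and
the optimizer are written against NumPy arrays in float32.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from platonet.dataset import NormalizationStats, OperatorDataset

__all__ = [
    "SurrogateSpec",
    "TrainingPlan",
    "SurrogateModel",
    "forward",
    "train",
    "predict_shape",
    "save_checkpoint",
    "load_checkpoint",
    "TrainingDivergence",
]


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class SurrogateSpec:
    """Architecture of the branch/trunk surrogate."""

    branch_hidden: tuple[int, ...] = (32, 16)
    trunk_hidden: tuple[int, ...] = (32, 32, 16)
    latent: int = 32
    branch_inputs: int = 2
    trunk_inputs: int = 4
    outputs: int = 3
    init_seed: int = 0

    def branch_layers(self) -> list[tuple[int, int]]:
        dims = [self.branch_inputs, *self.branch_hidden, self.latent]
        return list(zip(dims[:-1], dims[1:]))

    def trunk_layers(self) -> list[tuple[int, int]]:
        dims = [self.trunk_inputs, *self.trunk_hidden, self.latent]
        return list(zip(dims[:-1], dims[1:]))

    def parameter_count(self) -> int:
        """Closed-form parameter count (asserted against the built model)."""
        n = 0
        for fan_in, fan_out in self.branch_layers() + self.trunk_layers():
            n += fan_in * fan_out + fan_out
        n += self.latent * self.outputs + self.outputs  # readout
        return n


@dataclass
class TrainingPlan:
    """Optimization schedule: Adam + MSE + reduce-on-plateau."""

    epochs: int = 100
    learning_rate: float = 1e-3
    lr_floor: float = 1e-7
    batch_size: int = 128
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    plateau_min_delta: float = 0.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    shuffle_seed: int = 0


def _init_layers(layers: list[tuple[int, int]], rng: np.random.Generator):
    """Uniform fan-in initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    out = []
    for fan_in, fan_out in layers:
        bound = 1.0 / math.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(np.float32)
        b = rng.uniform(-bound, bound, size=fan_out).astype(np.float32)
        out.append([W, b])
    return out


@dataclass
class SurrogateModel:
    """Weights + spec + the normalization statistics they were fitted with."""

    spec: SurrogateSpec
    branch: list            # [[W, b], ...] with ReLU between, linear last
    trunk: list
    readout_W: np.ndarray   # (latent, outputs)
    readout_b: np.ndarray   # (outputs,)
    stats: NormalizationStats | None = None
    diameter: float = 1.0   # target length scale (platelet major diameter)

    @classmethod
    def initialize(
        cls,
        spec: SurrogateSpec,
        stats: NormalizationStats | None = None,
        diameter: float = 1.0,
    ) -> "SurrogateModel":
        rng = np.random.default_rng(spec.init_seed)
        branch = _init_layers(spec.branch_layers(), rng)
        trunk = _init_layers(spec.trunk_layers(), rng)
        bound = 1.0 / math.sqrt(spec.latent)
        W = rng.uniform(-bound, bound, size=(spec.latent, spec.outputs)).astype(
            np.float32
        )
        b = rng.uniform(-bound, bound, size=spec.outputs).astype(np.float32)
        model = cls(spec, branch, trunk, W, b, stats=stats, diameter=diameter)
        assert model.parameter_count() == spec.parameter_count()
        return model

    def parameter_count(self) -> int:
        n = sum(W.size + b.size for W, b in self.branch + self.trunk)
        return n + self.readout_W.size + self.readout_b.size

    def parameters(self) -> list[np.ndarray]:
        out = []
        for W, b in self.branch + self.trunk:
            out.extend([W, b])
        out.extend([self.readout_W, self.readout_b])
        return out

    def copy_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w


def _mlp_forward(x: np.ndarray, layers) -> tuple[np.ndarray, list]:
    """Forward pass keeping pre-activations for backprop."""
    cache = []
    h = x
    for k, (W, b) in enumerate(layers):
        z = h @ W + b
        if k < len(layers) - 1:
            a = np.maximum(z, 0.0)
        else:
            a = z
        cache.append((h, z))
        h = a
    return h, cache


def _mlp_backward(grad_out: np.ndarray, layers, cache) -> list:
    """Gradients per layer; returns [[dW, db], ...] matching ``layers``."""
    grads = [None] * len(layers)
    g = grad_out
    for k in range(len(layers) - 1, -1, -1):
        W, _ = layers[k]
        h, z = cache[k]
        if k < len(layers) - 1:
            g = g * (z > 0)
        grads[k] = [h.T @ g, g.sum(axis=0)]
        g = g @ W.T
    return grads


def forward(
    model: SurrogateModel, branch_in: np.ndarray, trunk_in: np.ndarray
) -> np.ndarray:
    """Normalized displacement prediction for normalized inputs.

    ``branch_in`` (n, 2) and ``trunk_in`` (n, 4) must already be min-max
    normalized with the model's stored statistics; the output is on the
    diameter-scaled displacement scale used for training targets.
    """
    branch_in = np.asarray(branch_in, dtype=np.float32)
    trunk_in = np.asarray(trunk_in, dtype=np.float32)
    if not (np.all(np.isfinite(branch_in)) and np.all(np.isfinite(trunk_in))):
        raise ValueError("non-finite inputs to the surrogate")
    b, _ = _mlp_forward(branch_in, model.branch)
    t, _ = _mlp_forward(trunk_in, model.trunk)
    return (b * t) @ model.readout_W + model.readout_b


def _forward_backward(model, bx, tx, y):
    """Loss and parameter gradients for one minibatch (MSE)."""
    b, bc = _mlp_forward(bx, model.branch)
    t, tc = _mlp_forward(tx, model.trunk)
    prod = b * t
    pred = prod @ model.readout_W + model.readout_b
    diff = pred - y
    n = y.size
    loss = float(np.mean(diff * diff))
    g = (2.0 / n) * diff
    dW3 = prod.T @ g
    db3 = g.sum(axis=0)
    dprod = g @ model.readout_W.T
    grads_b = _mlp_backward(dprod * t, model.branch, bc)
    grads_t = _mlp_backward(dprod * b, model.trunk, tc)
    flat = []
    for dW, db in grads_b + grads_t:
        flat.extend([dW, db])
    flat.extend([dW3, db3])
    return loss, flat


class _Adam:
    def __init__(self, params, plan: TrainingPlan):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.plan = plan

    def step(self, params, grads, lr):
        p1, p2, eps = self.plan.adam_beta1, self.plan.adam_beta2, self.plan.adam_eps
        self.t += 1
        bc1 = 1.0 - p1**self.t
        bc2 = 1.0 - p2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= p1
            m += (1.0 - p1) * g
            v *= p2
            v += (1.0 - p2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


def _evaluate(model, bx, tx, y, batch: int = 1 << 15) -> tuple[float, float]:
    """Full-set MSE and MAE, evaluated in chunks."""
    se = 0.0
    ae = 0.0
    n = len(y)
    for s in range(0, n, batch):
        pred = forward(model, bx[s : s + batch], tx[s : s + batch])
        d = pred - y[s : s + batch]
        se += float(np.sum(d * d))
        ae += float(np.sum(np.abs(d)))
    return se / (n * y.shape[1]), ae / (n * y.shape[1])


def train(
    spec: SurrogateSpec,
    plan: TrainingPlan,
    train_data: OperatorDataset,
    val_data: OperatorDataset,
    stats: NormalizationStats | None = None,
    verbose: bool = False,
) -> tuple[SurrogateModel, pd.DataFrame]:
    """Fit the surrogate; returns the best-validation checkpoint and history.

    ``stats`` must be fitted on the training partition only (it defaults to
    doing exactly that).  History rows carry per-epoch train MSE, validation
    MSE/MAE and the learning rate; epoch 0 records the untrained model.
    """
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("training and validation partitions must be non-empty")
    if stats is None:
        stats = NormalizationStats.fit(train_data)
    model = SurrogateModel.initialize(
        spec, stats=stats, diameter=train_data.diameter
    )

    bx = stats.normalize_branch(train_data.branch).astype(np.float32)
    tx = stats.normalize_trunk(train_data.trunk).astype(np.float32)
    y = train_data.target.astype(np.float32)
    bxv = stats.normalize_branch(val_data.branch).astype(np.float32)
    txv = stats.normalize_trunk(val_data.trunk).astype(np.float32)
    yv = val_data.target.astype(np.float32)

    rng = np.random.default_rng(plan.shuffle_seed)
    opt = _Adam(model.parameters(), plan)
    lr = plan.learning_rate
    best_val = math.inf
    best_weights = model.copy_weights()
    stagnant = 0
    rows = []

    val_mse0, val_mae0 = _evaluate(model, bxv, txv, yv)
    train_mse0, _ = _evaluate(model, bx, tx, y)
    rows.append(
        {"epoch": 0, "train_mse": train_mse0, "val_mse": val_mse0,
         "val_mae": val_mae0, "lr": lr}
    )

    n = len(y)
    for epoch in range(1, plan.epochs + 1):
        perm = rng.permutation(n)
        running = 0.0
        seen = 0
        params = model.parameters()
        for s in range(0, n, plan.batch_size):
            idx = perm[s : s + plan.batch_size]
            loss, grads = _forward_backward(model, bx[idx], tx[idx], y[idx])
            if not math.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite loss at epoch {epoch}; last finite train MSE "
                    f"{rows[-1]['train_mse']:.3e}, val MSE {rows[-1]['val_mse']:.3e}"
                )
            opt.step(params, grads, lr)
            running += loss * len(idx)
            seen += len(idx)
        val_mse, val_mae = _evaluate(model, bxv, txv, yv)
        rows.append(
            {"epoch": epoch, "train_mse": running / seen, "val_mse": val_mse,
             "val_mae": val_mae, "lr": lr}
        )
        if verbose:
            print(
                f"  epoch {epoch:3d}  train {running / seen:.3e}  "
                f"val {val_mse:.3e}  mae {val_mae:.3e}  lr {lr:.1e}",
                flush=True,
            )
        if val_mse < best_val - plan.plateau_min_delta:
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= plan.plateau_patience:
                lr = max(lr * plan.plateau_factor, plan.lr_floor)
                stagnant = 0
        if val_mse < best_val:
            best_val = val_mse
            best_weights = model.copy_weights()

    model.set_weights(best_weights)
    return model, pd.DataFrame(rows)


def predict_shape(
    model: SurrogateModel,
    x0_set: np.ndarray,
    t_hat: float,
    sigma: float,
    K: float,
) -> np.ndarray:
    """Deformed shell positions x0 + D*dx for all vertices at one instant.

    One branch evaluation is shared across all vertex queries at fixed
    (sigma, K); no time integration is involved.  ``t_hat`` outside [0, 1]
    is permitted (time extrapolation) but flagged with a warning.
    """
    if model.stats is None:
        raise ValueError("model carries no normalization statistics")
    if not 0.0 <= t_hat <= 1.0:
        import warnings

        warnings.warn(f"t_hat={t_hat} lies outside the trained range [0, 1]")
    x0_set = np.asarray(x0_set, dtype=float)
    n = len(x0_set)
    branch_in = model.stats.normalize_branch(np.array([[sigma, K]]))
    b, _ = _mlp_forward(branch_in.astype(np.float32), model.branch)
    trunk_raw = np.column_stack([x0_set, np.full(n, t_hat)])
    trunk_in = model.stats.normalize_trunk(trunk_raw).astype(np.float32)
    t, _ = _mlp_forward(trunk_in, model.trunk)
    dx = (b * t) @ model.readout_W + model.readout_b
    return x0_set + model.diameter * dx.astype(float)


# ------------------------------------------------------------- checkpointing


def save_checkpoint(model: SurrogateModel, path: str | Path) -> Path:
    """Self-describing checkpoint: weights + spec + normalization stats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "spec": {
            "branch_hidden": list(model.spec.branch_hidden),
            "trunk_hidden": list(model.spec.trunk_hidden),
            "latent": model.spec.latent,
            "branch_inputs": model.spec.branch_inputs,
            "trunk_inputs": model.spec.trunk_inputs,
            "outputs": model.spec.outputs,
            "init_seed": model.spec.init_seed,
        },
        "stats": None if model.stats is None else model.stats.to_dict(),
        "diameter": model.diameter,
    }
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    with open(path, "wb") as fh:  # honour the exact path (no .npz appended)
        np.savez(fh, header=json.dumps(header), **arrays)
    return path


def load_checkpoint(path: str | Path) -> SurrogateModel:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        spec = SurrogateSpec(
            branch_hidden=tuple(header["spec"]["branch_hidden"]),
            trunk_hidden=tuple(header["spec"]["trunk_hidden"]),
            latent=header["spec"]["latent"],
            branch_inputs=header["spec"]["branch_inputs"],
            trunk_inputs=header["spec"]["trunk_inputs"],
            outputs=header["spec"]["outputs"],
            init_seed=header["spec"]["init_seed"],
        )
        stats = (
            None
            if header["stats"] is None
            else NormalizationStats.from_dict(header["stats"])
        )
        model = SurrogateModel.initialize(
            spec, stats=stats, diameter=header["diameter"]
        )
        weights = [data[f"p{i}"] for i in range(len(model.parameters()))]
    model.set_weights(weights)
    return model
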