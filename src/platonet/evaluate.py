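"""Surrogate error analysis: percentile tables, time/curvature structure,
and the leave-extremes-out extrapolation study.

The relative displacement error of a prediction is

    e_i = || x_hat_i - x_i || / D,

with D the platelet's rest major diameter — a fixed length normalization,
so errors are comparable across snapshots (a per-sample division by the
instantaneous true displacement would diverge at t -> 0).  Per-stiffness
reports give the median, 90th percentile and maximum over all validation
samples of that stiffness; percentiles use linear interpolation between
order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from platonet.dataset import (
    NormalizationStats,
    OperatorDataset,
    assemble,
    leave_extremes_out,
    random_split,
)
from platonet.deeponet import (
    SurrogateModel,
    SurrogateSpec,
    TrainingPlan,
    forward,
    predict_shape,
    train,
)
from platonet.geometry import PlateletGeometry, curvature_proxy
from platonet.simulate import Trajectory

__all__ = [
    "ErrorReport",
    "relative_error",
    "sample_errors",
    "per_K_report",
    "pooled_percentiles",
    "time_resolved_error",
    "curvature_binned_error",
    "extrapolation_study",
]


@dataclass
class ErrorReport:
    """Per-stiffness percentile rows plus optional error structure tables."""

    rows: pd.DataFrame                      # K, Ca, err_p50, err_p90, err_max
    pooled: dict = field(default_factory=dict)
    time_curves: dict = field(default_factory=dict)   # K -> (n_snap,) mean error
    histograms: dict = field(default_factory=dict)    # label -> (edges, counts)

    def __post_init__(self) -> None:
        r = self.rows
        if len(r):
            if (r["err_p50"] > r["err_p90"] + 1e-15).any() or (
                r["err_p90"] > r["err_max"] + 1e-15
            ).any():
                raise ValueError("percentile ordering violated in report rows")
            if (r[["err_p50", "err_p90", "err_max"]] < 0).any().any():
                raise ValueError("errors must be non-negative")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(path, index=False, float_format="%.4f")
        return path


def relative_error(
    predicted: np.ndarray, true: np.ndarray, norm_length: float
) -> np.ndarray:
    """Per-vertex relative displacement errors ||x_hat - x|| / norm_length."""
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape:
        raise ValueError("prediction/truth shape mismatch")
    if norm_length <= 0:
        raise ValueError("norm_length must be positive")
    return np.linalg.norm(predicted - true, axis=-1) / norm_length


def sample_errors(model: SurrogateModel, data: OperatorDataset) -> np.ndarray:
    """Relative displacement error of every sample in a dataset.

    Targets and predictions are on the diameter-normalized displacement
    scale, so the prediction-minus-target magnitude *is* the relative error.
    """
    if model.stats is None:
        raise ValueError("model carries no normalization statistics")
    bx = model.stats.normalize_branch(data.branch)
    tx = model.stats.normalize_trunk(data.trunk)
    err = np.empty(len(data))
    chunk = 1 << 15
    for s in range(0, len(data), chunk):
        pred = forward(model, bx[s : s + chunk], tx[s : s + chunk])
        err[s : s + chunk] = np.linalg.norm(
            pred - data.target[s : s + chunk], axis=1
        )
    return err


def _percentile_row(err: np.ndarray) -> dict:
    # linear interpolation between order statistics (fixed for 4-decimal
    # reproducibility of the report formatting)
    return {
        "err_p50": float(np.percentile(err, 50, method="linear")),
        "err_p90": float(np.percentile(err, 90, method="linear")),
        "err_max": float(np.max(err)),
    }


def per_K_report(model: SurrogateModel, data: OperatorDataset) -> ErrorReport:
    """Median / 90th percentile / maximum error per stiffness level.

    ``data`` is typically the validation partition: time instants and
    vertex indices never seen during training, at every trained K.
    """
    err = sample_errors(model, data)
    rows = []
    for k in range(len(data.K_values)):
        sel = data.traj_index == k
        if not np.any(sel):
            raise ValueError(f"no samples for stiffness index {k} in dataset")
        rows.append(
            {
                "K": data.K_values[k],
                "Ca": data.Ca_values[k],
                **_percentile_row(err[sel]),
            }
        )
    frame = pd.DataFrame(rows).sort_values("Ca", ascending=False, ignore_index=True)
    return ErrorReport(rows=frame, pooled=_percentile_row(err))


def pooled_percentiles(model: SurrogateModel, data: OperatorDataset) -> dict:
    """Median/p90/max of the pooled per-sample error distribution."""
    return _percentile_row(sample_errors(model, data))


def time_resolved_error(
    model: SurrogateModel, trajectory: Trajectory, sigma: float | None = None
) -> np.ndarray:
    """Space-averaged relative error at each snapshot of one trajectory."""
    sigma = trajectory.sigma_w if sigma is None else sigma
    th = trajectory.t_hat()
    x0 = trajectory.x0
    out = np.empty(trajectory.n_snapshots)
    for s in range(trajectory.n_snapshots):
        pred = predict_shape(model, x0, float(th[s]), sigma, trajectory.K)
        out[s] = float(
            np.mean(
                relative_error(pred, trajectory.positions[s], trajectory.major_diameter)
            )
        )
    return out


def curvature_binned_error(
    model: SurrogateModel,
    trajectory: Trajectory,
    geom: PlateletGeometry,
    snapshot_index: int | None = None,
    bins: tuple[int, int] = (20, 20),
) -> dict:
    """2-D histogram of (curvature proxy, point-wise error) at one snapshot.

    The curvature proxy is the mean distance to bonded neighbours evaluated
    at the snapshot's true (deformed) positions; the default snapshot is the
    argmax of the time-resolved error curve — the moment the surrogate finds
    hardest, typically first membrane self-contact.
    """
    if snapshot_index is None:
        snapshot_index = int(np.argmax(time_resolved_error(model, trajectory)))
    true = trajectory.positions[snapshot_index]
    proxy = curvature_proxy(geom, true)
    pred = predict_shape(
        model, trajectory.x0, float(trajectory.t_hat()[snapshot_index]),
        trajectory.sigma_w, trajectory.K,
    )
    err = relative_error(pred, true, trajectory.major_diameter)
    counts, pe, ee = np.histogram2d(proxy, err, bins=bins)
    return {
        "snapshot_index": snapshot_index,
        "proxy": proxy,
        "error": err,
        "counts": counts,
        "proxy_edges": pe,
        "error_edges": ee,
    }


def evaluate_on_trajectories(
    model: SurrogateModel, trajs: list[Trajectory]
) -> np.ndarray:
    """Pooled per-sample errors over complete trajectories (all snapshots)."""
    data = assemble(trajs)
    return sample_errors(model, data)


def extrapolation_study(
    trajs: list[Trajectory],
    spec: SurrogateSpec,
    plan: TrainingPlan,
    train_fraction: float = 0.9,
    split_seed: int = 0,
    hist_bins: int = 40,
    verbose: bool = False,
) -> ErrorReport:
    """Leave-extremes-out retraining and evaluation on the held-out pair.

    The stiffest and most compliant trajectories are excluded from both
    fitting and normalization statistics; a fresh surrogate is trained on
    the remainder with identical hyper-parameters and evaluated solely on
    the excluded capillary numbers.
    """
    kept, held = leave_extremes_out(trajs)
    data = assemble(kept)
    tr, va, _ = random_split(data, train_fraction, seed=split_seed)
    model, history = train(spec, plan, tr, va, verbose=verbose)

    rows = []
    hists = {}
    errs_all = []
    for tr_h in sorted(held, key=lambda t: t.K):
        err = evaluate_on_trajectories(model, [tr_h])
        errs_all.append(err)
        label = "stiff" if tr_h.K == max(t.K for t in held) else "compliant"
        rows.append(
            {"K": tr_h.K, "Ca": tr_h.Ca, "case": label, **_percentile_row(err)}
        )
        hists[label] = np.histogram(err, bins=hist_bins)
    pooled = _percentile_row(np.concatenate(errs_all))
    combined = np.concatenate(errs_all)
    hists["combined"] = np.histogram(combined, bins=hist_bins)
    frame = pd.DataFrame(rows)
    report = ErrorReport(
        rows=frame[["K", "Ca", "err_p50", "err_p90", "err_max"]],
        pooled=pooled,
        histograms=hists,
    )
    report.rows = frame  # keep the case labels
    return report
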