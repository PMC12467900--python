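"""End-to-end pipeline: sweep generation -> training -> error reports.

A single master seed fans out to per-stage seeds (geometry, per-trajectory
noise, split shuffling, weight initialization) through
:func:`platonet.config.derive_seed`, so the whole experiment is reproducible
from one integer.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from platonet import __version__
from platonet.config import ExperimentConfig, derive_seed
from platonet.dataset import (
    NormalizationStats,
    OperatorDataset,
    assemble,
    random_split,
)
from platonet.deeponet import (
    SurrogateModel,
    SurrogateSpec,
    TrainingPlan,
    save_checkpoint,
    train,
)
from platonet.evaluate import ErrorReport, extrapolation_study, per_K_report
from platonet.geometry import build_ellipsoid_shell
from platonet.simulate import Trajectory, run_sweep, save_trajectories

__all__ = ["PipelineResult", "surrogate_spec", "training_plan",
           "run_interpolation", "run_extrapolation", "write_manifest"]


@dataclass
class PipelineResult:
    """Artifacts of one generate -> train -> evaluate pass."""

    config: ExperimentConfig
    trajectories: list[Trajectory]
    dataset: OperatorDataset
    train_data: OperatorDataset
    val_data: OperatorDataset
    model: SurrogateModel
    history: pd.DataFrame
    report: ErrorReport
    geometry: object = None


def surrogate_spec(cfg: ExperimentConfig) -> SurrogateSpec:
    return SurrogateSpec(init_seed=derive_seed(cfg.seed, "init"))


def training_plan(cfg: ExperimentConfig) -> TrainingPlan:
    return TrainingPlan(
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        lr_floor=cfg.lr_floor,
        batch_size=cfg.batch_size,
        shuffle_seed=derive_seed(cfg.seed, "shuffle"),
    )


def run_interpolation(
    cfg: ExperimentConfig, verbose: bool = False
) -> PipelineResult:
    """Full interpolation experiment at the configured desk scale."""
    geom = build_ellipsoid_shell(
        cfg.semi_axes, cfg.n_membrane, seed=derive_seed(cfg.seed, "geometry")
    )
    t0 = time.time()
    trajs = run_sweep(cfg, geom=geom, progress=verbose)
    if verbose:
        print(f"[pipeline] sweep done in {time.time() - t0:.0f} s", flush=True)
    data = assemble(trajs)
    tr, va, _ = random_split(
        data, cfg.train_fraction, seed=derive_seed(cfg.seed, "split")
    )
    model, history = train(
        surrogate_spec(cfg), training_plan(cfg), tr, va, verbose=verbose
    )
    report = per_K_report(model, va)
    return PipelineResult(
        config=cfg, trajectories=trajs, dataset=data, train_data=tr,
        val_data=va, model=model, history=history, report=report,
        geometry=geom,
    )


def run_extrapolation(
    cfg: ExperimentConfig, trajs: list[Trajectory], verbose: bool = False
) -> ErrorReport:
    """Leave-extremes-out retraining with baseline hyper-parameters."""
    return extrapolation_study(
        trajs,
        surrogate_spec(cfg),
        training_plan(cfg),
        train_fraction=cfg.train_fraction,
        split_seed=derive_seed(cfg.seed, "split-extrapolation"),
        verbose=verbose,
    )


def write_manifest(
    outdir: str | Path, cfg: ExperimentConfig, artifacts: dict[str, str]
) -> Path:
    """Run manifest: config hash, seeds, version, artifact paths, timestamp."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "master_seed": cfg.seed,
        "platonet_version": __version__,
        "artifacts": artifacts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
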