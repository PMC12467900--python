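"""Supervised operator-learning samples from membrane trajectories.

Each (trajectory, snapshot, vertex) triple becomes one sample of the
operator G: (x0, t; sigma, K) -> x(t), stored in flat arrays:

* branch input  (sigma_w, K)            -- the flow/material parameters,
* trunk input   (x0, t_hat)             -- query vertex and t_hat = t/T in [0, 1],
* target        dx = (x(t) - x0) / D    -- displacement scaled by the
                                           platelet major diameter D.

Targets are displacements rather than absolute positions so the t = 0
contract (zero output) is exact by construction; predicted positions are
reconstructed as x0 + D * dx.  Inputs are min-max normalized with
statistics fitted on the training partition only and reused unchanged at
validation/inference time; a constant channel (the single wall stress
sigma_w) maps to 0 by convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import h5py
import numpy as np

from platonet.simulate import Trajectory

__all__ = [
    "OperatorSample",
    "OperatorDataset",
    "NormalizationStats",
    "assemble",
    "random_split",
    "leave_extremes_out",
    "save_dataset",
    "load_dataset",
]

BRANCH_CHANNELS = ("sigma_w", "K")
TRUNK_CHANNELS = ("x0", "y0", "z0", "t_hat")


class OperatorSample(NamedTuple):
    """A single (branch, trunk, target) sample."""

    branch: np.ndarray   # (2,)
    trunk: np.ndarray    # (4,)
    target: np.ndarray   # (3,)


@dataclass
class OperatorDataset:
    """Column-oriented container of operator samples.

    Group tags (trajectory, snapshot, vertex index per sample) are kept so
    per-stiffness and per-snapshot error reports can be assembled without
    re-simulating.
    """

    branch: np.ndarray       # (n, 2) float
    trunk: np.ndarray        # (n, 4) float
    target: np.ndarray       # (n, 3) float
    traj_index: np.ndarray   # (n,) int
    snap_index: np.ndarray   # (n,) int
    vertex_index: np.ndarray  # (n,) int
    K_values: np.ndarray     # (n_traj,) stiffness per trajectory index
    Ca_values: np.ndarray    # (n_traj,)
    diameter: float          # target length normalization

    def __len__(self) -> int:
        return len(self.branch)

    def __getitem__(self, i: int) -> OperatorSample:
        return OperatorSample(self.branch[i], self.trunk[i], self.target[i])

    def subset(self, idx: np.ndarray) -> "OperatorDataset":
        return OperatorDataset(
            branch=self.branch[idx], trunk=self.trunk[idx],
            target=self.target[idx], traj_index=self.traj_index[idx],
            snap_index=self.snap_index[idx], vertex_index=self.vertex_index[idx],
            K_values=self.K_values, Ca_values=self.Ca_values,
            diameter=self.diameter,
        )


def assemble(trajs: Sequence[Trajectory]) -> OperatorDataset:
    """One sample per (trajectory, snapshot, vertex).

    All trajectories must share the vertex count and snapshot schedule; the
    sample count is n_traj * n_snap * n_vertices and every t_hat = 0 sample
    has an exactly zero target.
    """
    if not trajs:
        raise ValueError("no trajectories to assemble")
    n_v = trajs[0].n_vertices
    n_s = trajs[0].n_snapshots
    for tr in trajs:
        if tr.n_vertices != n_v or tr.n_snapshots != n_s:
            raise ValueError(
                "trajectories disagree on vertex count or snapshot schedule"
            )
    D = trajs[0].major_diameter
    branch, trunk, target = [], [], []
    ti, si, vi = [], [], []
    for k, tr in enumerate(trajs):
        x0 = tr.x0
        th = tr.t_hat()
        disp = tr.displacements() / D
        for s in range(n_s):
            branch.append(np.broadcast_to([tr.sigma_w, tr.K], (n_v, 2)))
            trunk.append(
                np.column_stack([x0, np.full(n_v, th[s])])
            )
            target.append(disp[s])
            ti.append(np.full(n_v, k))
            si.append(np.full(n_v, s))
            vi.append(np.arange(n_v))
    return OperatorDataset(
        branch=np.vstack(branch).astype(np.float64),
        trunk=np.vstack(trunk).astype(np.float64),
        target=np.vstack(target).astype(np.float64),
        traj_index=np.concatenate(ti).astype(np.int32),
        snap_index=np.concatenate(si).astype(np.int32),
        vertex_index=np.concatenate(vi).astype(np.int32),
        K_values=np.array([tr.K for tr in trajs]),
        Ca_values=np.array([tr.Ca for tr in trajs]),
        diameter=D,
    )


def random_split(
    dataset: OperatorDataset, train_fraction: float = 0.9, seed: int = 0
) -> tuple[OperatorDataset, OperatorDataset, dict]:
    """Uniformly random, disjoint and exhaustive train/validation split.

    Sampling is uniform over (trajectory, snapshot, vertex) tuples, so every
    stiffness level appears in training; the returned manifest records the
    permutation seed and sizes for reproducibility.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    n_train = int(round(train_fraction * len(dataset)))
    train_idx = np.sort(perm[:n_train])
    val_idx = np.sort(perm[n_train:])
    manifest = {
        "seed": int(seed),
        "train_fraction": float(train_fraction),
        "n_total": len(dataset),
        "n_train": int(n_train),
        "n_val": int(len(dataset) - n_train),
    }
    return dataset.subset(train_idx), dataset.subset(val_idx), manifest


def leave_extremes_out(
    trajs: Sequence[Trajectory],
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Hold out the stiffest and most compliant trajectories (extreme Ca*).

    The held-out pair is excluded from fitting *and* from normalization
    statistics, making evaluation on them a pure extrapolation test.
    """
    ks = [tr.K for tr in trajs]
    if len(set(ks)) < 3:
        raise ValueError("leave-extremes-out needs at least 3 distinct K levels")
    k_min, k_max = min(ks), max(ks)
    held = [tr for tr in trajs if tr.K in (k_min, k_max)]
    kept = [tr for tr in trajs if tr.K not in (k_min, k_max)]
    return kept, held


@dataclass
class NormalizationStats:
    """Per-input-channel min-max statistics (fitted on training data only).

    Degenerate channels (max == min, e.g. the constant wall stress) are
    mapped to 0 by convention.
    """

    branch_min: np.ndarray
    branch_max: np.ndarray
    trunk_min: np.ndarray
    trunk_max: np.ndarray

    @classmethod
    def fit(cls, dataset: OperatorDataset) -> "NormalizationStats":
        return cls(
            branch_min=dataset.branch.min(axis=0),
            branch_max=dataset.branch.max(axis=0),
            trunk_min=dataset.trunk.min(axis=0),
            trunk_max=dataset.trunk.max(axis=0),
        )

    @staticmethod
    def _apply(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        span = hi - lo
        safe = np.where(span > 0, span, 1.0)
        out = (x - lo) / safe
        return np.where(span > 0, out, 0.0)

    @staticmethod
    def _invert(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        span = hi - lo
        return np.where(span > 0, x * span + lo, lo)

    def normalize_branch(self, b: np.ndarray) -> np.ndarray:
        return self._apply(b, self.branch_min, self.branch_max)

    def normalize_trunk(self, t: np.ndarray) -> np.ndarray:
        return self._apply(t, self.trunk_min, self.trunk_max)

    def denormalize_branch(self, b: np.ndarray) -> np.ndarray:
        return self._invert(b, self.branch_min, self.branch_max)

    def denormalize_trunk(self, t: np.ndarray) -> np.ndarray:
        return self._invert(t, self.trunk_min, self.trunk_max)

    def normalize(self, ds: OperatorDataset) -> OperatorDataset:
        out = ds.subset(np.arange(len(ds)))
        out.branch = self.normalize_branch(ds.branch)
        out.trunk = self.normalize_trunk(ds.trunk)
        return out

    def to_dict(self) -> dict:
        return {
            "branch_min": self.branch_min.tolist(),
            "branch_max": self.branch_max.tolist(),
            "trunk_min": self.trunk_min.tolist(),
            "trunk_max": self.trunk_max.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


# ------------------------------------------------------------------ storage


def save_dataset(
    dataset: OperatorDataset,
    path: str | Path,
    stats: NormalizationStats | None = None,
    manifest: dict | None = None,
) -> Path:
    """Write the columnar dataset (HDF5 layout: /branch /trunk /target /meta)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("branch", data=dataset.branch)
        f.create_dataset("trunk", data=dataset.trunk)
        f.create_dataset("target", data=dataset.target)
        meta = f.create_group("meta")
        meta.create_dataset("traj_index", data=dataset.traj_index)
        meta.create_dataset("snap_index", data=dataset.snap_index)
        meta.create_dataset("vertex_index", data=dataset.vertex_index)
        meta.create_dataset("K_values", data=dataset.K_values)
        meta.create_dataset("Ca_values", data=dataset.Ca_values)
        meta.attrs["diameter"] = dataset.diameter
        if stats is not None:
            meta.attrs["normalization"] = json.dumps(stats.to_dict())
        if manifest is not None:
            meta.attrs["manifest"] = json.dumps(manifest)
    return path


def load_dataset(
    path: str | Path,
) -> tuple[OperatorDataset, NormalizationStats | None, dict | None]:
    with h5py.File(path, "r") as f:
        meta = f["meta"]
        ds = OperatorDataset(
            branch=f["branch"][:], trunk=f["trunk"][:], target=f["target"][:],
            traj_index=meta["traj_index"][:], snap_index=meta["snap_index"][:],
            vertex_index=meta["vertex_index"][:],
            K_values=meta["K_values"][:], Ca_values=meta["Ca_values"][:],
            diameter=float(meta.attrs["diameter"]),
        )
        stats = None
        if "normalization" in meta.attrs:
            stats = NormalizationStats.from_dict(json.loads(meta.attrs["normalization"]))
        manifest = json.loads(meta.attrs["manifest"]) if "manifest" in meta.attrs else None
    return ds, stats, manifest
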