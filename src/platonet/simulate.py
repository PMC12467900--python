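"""Couette-flow platelet runs across the stiffness sweep.

Each run places the triangulated shell at the centre of the sheared box
with its flat faces in the flow-vorticity (x-z) plane, equilibrates without
shear, starts the walls impulsively together with the linear Couette
profile, and then records the membrane vertex positions at ``n_snap``
uniform times over one analytic Jeffery period of the 1:4 spheroid.

Bond stiffnesses are swept in SI units (N/m) and mapped to reduced engine
units by the configured stiffness scale; each trajectory is tagged with its
capillary number Ca* = C/K, with the calibration constant C anchored to the
softest level of the reference sweep (Ca* = 0.7698 at K = 0.0003 N/m).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from platonet import xyz
from platonet.config import ExperimentConfig, derive_seed, write_config
from platonet.dpd import (
    FLUID,
    MEMBRANE,
    WALL_BOT,
    WALL_TOP,
    CouplingParams,
    FluidParams,
    ParticleState,
    check_nyquist,
    compute_all_forces,
    step,
)
from platonet.geometry import PlateletGeometry, build_ellipsoid_shell

__all__ = [
    "Trajectory",
    "capillary_number",
    "jeffery_period",
    "create_couette_state",
    "run_trajectory",
    "run_sweep",
    "save_trajectories",
    "load_trajectories",
]

#: Calibration constant of Ca* = C/K, anchored at the (K = 0.0003 N/m,
#: Ca* = 0.7698) row of the reference sweep.
CA_CALIBRATION = 0.7698 * 0.0003


def capillary_number(K: float, calibration_constant: float = CA_CALIBRATION) -> float:
    """Capillary number Ca* = C/K for bond stiffness K in N/m.

    Ca* measures the ratio of viscous to elastic forces on the platelet;
    softer bonds (smaller K) give larger Ca*.
    """
    if K <= 0:
        raise ValueError(f"bond stiffness must be positive, got {K}")
    return calibration_constant / K


def jeffery_period(aspect_ratio: float, shear_rate: float) -> float:
    """Tumbling period T_J = (2 pi / gamma_dot) (r_e + 1/r_e) of a spheroid.

    ``aspect_ratio`` is the spheroid axis ratio r_e (thickness/diameter =
    1/4 for the platelet); the formula is symmetric under r_e -> 1/r_e.
    """
    if aspect_ratio <= 0:
        raise ValueError("aspect ratio must be positive")
    if shear_rate <= 0:
        raise ValueError("shear rate must be positive: no Jeffery orbit at rest")
    return (2.0 * math.pi / shear_rate) * (aspect_ratio + 1.0 / aspect_ratio)


@dataclass
class Trajectory:
    """One recorded membrane trajectory of the stiffness sweep."""

    K: float                     # bond stiffness [N/m]
    K_reduced: float             # engine stiffness [reduced]
    Ca: float                    # capillary number tag
    sigma_w: float               # wall shear stress [Pa]
    times: np.ndarray            # (n_snap,) reduced times, t[0] = 0
    positions: np.ndarray        # (n_snap, V, 3) membrane vertices
    seed: int
    jeffery_T: float             # analytic period used to set run length
    duration: float              # actual recorded duration (~= jeffery_T)
    shear_rate: float            # reduced gamma_dot
    major_diameter: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions disagree on snapshot count")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must start at 0 and strictly increase")

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    @property
    def n_vertices(self) -> int:
        return self.positions.shape[1]

    @property
    def x0(self) -> np.ndarray:
        """Initial vertex positions; identical to the t=0 snapshot."""
        return self.positions[0]

    def displacements(self) -> np.ndarray:
        """(n_snap, V, 3) displacement field x(t) - x0."""
        return self.positions - self.positions[0]

    def t_hat(self) -> np.ndarray:
        """Dimensionless times t / T, uniform on [0, 1]."""
        return self.times / self.duration


# ----------------------------------------------------------- state assembly


def _ellipsoid_inside(points: np.ndarray, center: np.ndarray,
                      axes: tuple[float, float, float], margin: float) -> np.ndarray:
    d = (points - center) / (np.asarray(axes) + margin)
    return np.sum(d * d, axis=1) < 1.0


def create_couette_state(
    cfg: ExperimentConfig,
    geom: PlateletGeometry | None,
    seed: int,
    periodic_y: bool = False,
    with_walls: bool = True,
) -> ParticleState:
    """Assemble fluid, optional membrane, and wall slabs.

    Fluid particles are placed uniformly outside the platelet (margin one
    LJ length) with Maxwell-Boltzmann velocities; wall slabs of thickness
    ``wall_thickness`` sit beyond y = +-Ly/2 and later translate rigidly at
    +-U.  The membrane is centred in the box with its short axis along the
    velocity-gradient (y) direction.
    """
    rng = np.random.default_rng(seed)
    Lx, Ly, Lz = cfg.Lx, cfg.Ly, cfg.Lz
    center = np.array([Lx / 2.0, 0.0, Lz / 2.0])

    mem_pos = np.empty((0, 3))
    axes_engine: tuple[float, float, float] | None = None
    if geom is not None:
        g = geom.positions
        # geometry frame: short axis along its z; engine: short axis along y
        mem_pos = center + np.column_stack([g[:, 0], g[:, 2], g[:, 1]])
        a, b, c = geom.semi_axes
        axes_engine = (a, c, b)

    # solvent fills the whole gap, platelet interior included (a membrane
    # separates two fluid compartments; an empty interior would leave the
    # shell to bear the full fluid pressure and collapse) -- only a thin
    # band around the membrane surface is kept clear of the LJ cores
    v_excl = 0.0
    if axes_engine is not None:
        ax = np.asarray(axes_engine)
        v_excl = 4.0 / 3.0 * math.pi * (
            float(np.prod(ax + cfg.sigma_lj))
            - float(np.prod(np.maximum(ax - cfg.sigma_lj, 0.0)))
        )
    n_fluid_target = int(round(cfg.rho_f * (Lx * Ly * Lz - v_excl)))
    pts = []
    n_have = 0
    while n_have < n_fluid_target:
        cand = rng.uniform(0, 1, size=(2 * n_fluid_target, 3))
        cand[:, 0] *= Lx
        cand[:, 1] = (cand[:, 1] - 0.5) * Ly
        cand[:, 2] *= Lz
        if axes_engine is not None:
            in_band = _ellipsoid_inside(
                cand, center, axes_engine, cfg.sigma_lj
            ) & ~_ellipsoid_inside(cand, center, axes_engine, -cfg.sigma_lj)
            cand = cand[~in_band]
        pts.append(cand)
        n_have += len(cand)
    fluid_pos = np.vstack(pts)[:n_fluid_target]

    wall_pos = np.empty((0, 3))
    wall_species = np.empty(0, dtype=np.int8)
    if with_walls and not periodic_y:
        n_wall = int(round(cfg.wall_density * Lx * cfg.wall_thickness * Lz))
        for sp, ylo in ((WALL_TOP, Ly / 2.0), (WALL_BOT, -Ly / 2.0 - cfg.wall_thickness)):
            w = rng.uniform(0, 1, size=(n_wall, 3))
            w[:, 0] *= Lx
            w[:, 1] = ylo + w[:, 1] * cfg.wall_thickness
            w[:, 2] *= Lz
            wall_pos = np.vstack([wall_pos, w])
            wall_species = np.concatenate(
                [wall_species, np.full(n_wall, sp, dtype=np.int8)]
            )

    nf, nm, nw = len(fluid_pos), len(mem_pos), len(wall_pos)
    positions = np.vstack([fluid_pos, mem_pos, wall_pos]) if nm or nw else fluid_pos
    species = np.concatenate([
        np.zeros(nf, dtype=np.int8),
        np.full(nm, MEMBRANE, dtype=np.int8),
        wall_species,
    ])
    mass = np.concatenate([
        np.ones(nf),
        np.full(nm, cfg.membrane_mass),
        np.ones(nw),
    ])
    vel = np.zeros((len(positions), 3))
    vth = math.sqrt(cfg.kBT)
    vel[:nf] = rng.normal(0.0, vth, size=(nf, 3))
    vel[:nf] -= vel[:nf].mean(axis=0)
    vel[nf : nf + nm] = rng.normal(
        0.0, math.sqrt(cfg.kBT / cfg.membrane_mass), size=(nm, 3)
    )

    excl = None
    if geom is not None:
        max_deg = int(geom.degree().max())
        excl = -np.ones((nm, max_deg), dtype=np.int64)
        for v, nbr in enumerate(geom.neighbors):
            excl[v, : len(nbr)] = nbr + nf

    return ParticleState(
        positions=positions,
        velocities=vel,
        species=species,
        mass=mass,
        box=(Lx, Ly, Lz),
        n_fluid=nf,
        n_membrane=nm,
        wall_speed=0.0,
        periodic_y=periodic_y,
        noise_seed=derive_seed(seed, "pair-noise"),
        bond_exclusions=excl,
    )


def _fluid_params(cfg: ExperimentConfig) -> FluidParams:
    return FluidParams(
        gamma_hat=cfg.gamma_hat, kBT=cfg.kBT, rho_f=cfg.rho_f,
        r_c=cfg.r_c, m=1.0, alpha_hat=cfg.alpha_hat,
    )


def _coupling_params(
    cfg: ExperimentConfig, geom: PlateletGeometry | None = None
) -> CouplingParams:
    # membrane self-contact LJ length scales with the mesh so the rest
    # shell is (nearly) self-force-free at any resolution
    sigma_mm = None
    if geom is not None:
        sigma_mm = cfg.sigma_mm_factor * float(geom.rest_lengths.min())
    return CouplingParams(
        eps_lj=cfg.eps_lj, sigma_lj=cfg.sigma_lj, lj_cutoff=cfg.lj_cutoff,
        gamma_hat_m=cfg.gamma_hat_m, kBT=cfg.kBT,
        sigma_mm=sigma_mm,
        mm_cutoff=None if sigma_mm is None else 2.5 * sigma_mm,
        eps_mm=cfg.eps_mm,
    )


def _unwrap_membrane(pos_mem: np.ndarray, box, reference: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping of membrane coordinates.

    Each vertex is placed at the periodic image closest to its position in
    the ``reference`` frame (the previous snapshot, or the box-centred rest
    shape for the first one), so recorded trajectories stay continuous even
    when the platelet migrates across a periodic boundary.
    """
    Lx, _, Lz = box
    out = pos_mem.copy()
    for axis, L in ((0, Lx), (2, Lz)):
        d = out[:, axis] - reference[:, axis]
        out[:, axis] -= L * np.rint(d / L)
    return out


def start_shear(state: ParticleState, cfg: ExperimentConfig) -> None:
    """Start the walls and superpose the steady linear Couette profile.

    The linear profile v_x = gamma_dot * y is the steady solution of the
    sheared gap, so starting the run on it avoids waiting out the slow
    momentum-diffusion transient of a quiescent start.
    """
    state.wall_speed = cfg.wall_speed
    mobile = state.mobile
    state.velocities[mobile, 0] += cfg.shear_rate_reduced * state.positions[mobile, 1]
    top = state.species == WALL_TOP
    bot = state.species == WALL_BOT
    state.velocities[top] = 0.0
    state.velocities[bot] = 0.0
    state.velocities[top, 0] = cfg.wall_speed
    state.velocities[bot, 0] = -cfg.wall_speed
    state.forces = None  # force cache invalid after the velocity jump


def run_trajectory(
    cfg: ExperimentConfig,
    K: float,
    seed: int,
    geom: PlateletGeometry | None = None,
    n_snap: int | None = None,
    duration: float | None = None,
    callback=None,
) -> Trajectory:
    """Simulate one stiffness level and record its membrane snapshots.

    ``K`` is in N/m; the run covers one analytic Jeffery period of the 1:4
    spheroid at the configured reduced shear rate, after a zero-shear
    equilibration and a short sheared settling phase.  Deterministic for a
    fixed seed.
    """
    if geom is None:
        geom = build_ellipsoid_shell(
            cfg.semi_axes, cfg.n_membrane, seed=derive_seed(cfg.seed, "geometry")
        )
    n_snap = cfg.n_snap if n_snap is None else n_snap
    K_red = cfg.stiffness_reduced(K)
    z_max = int(geom.degree().max())
    check_nyquist(cfg.dt, K_red, z_max, cfg.membrane_mass)

    params = _fluid_params(cfg)
    coupling = _coupling_params(cfg, geom)
    state = create_couette_state(cfg, geom, seed)
    bonds, rest = geom.bonds, geom.rest_lengths

    def advance(n_steps: int) -> None:
        for _ in range(n_steps):
            step(
                state, params, cfg.dt, coupling, bonds, rest, K_red,
                velocity_ceiling=cfg.velocity_ceiling,
            )

    advance(cfg.warmup_steps)
    start_shear(state, cfg)
    advance(cfg.shear_warmup_steps)

    a_long = max(cfg.semi_axes)
    a_short = min(cfg.semi_axes)
    if cfg.shear_rate_reduced > 0:
        T_J = jeffery_period(a_short / a_long, cfg.shear_rate_reduced)
    elif duration is None:
        raise ValueError("zero shear rate: an explicit duration is required")
    span = T_J if duration is None else duration
    if cfg.shear_rate_reduced <= 0:
        T_J = span
    steps_per_snap = max(1, round(span / ((n_snap - 1) * cfg.dt)))
    duration = (n_snap - 1) * steps_per_snap * cfg.dt

    snaps = np.empty((n_snap, state.n_membrane, 3))
    times = np.empty(n_snap)
    snaps[0] = state.membrane_positions()
    times[0] = 0.0
    for k in range(1, n_snap):
        advance(steps_per_snap)
        snaps[k] = _unwrap_membrane(state.membrane_positions(), state.box, snaps[k - 1])
        times[k] = k * steps_per_snap * cfg.dt
        if callback is not None:
            callback(k, state)

    return Trajectory(
        K=K,
        K_reduced=K_red,
        Ca=capillary_number(K),
        sigma_w=cfg.sigma_w,
        times=times,
        positions=snaps,
        seed=seed,
        jeffery_T=T_J,
        duration=duration,
        shear_rate=cfg.shear_rate_reduced,
        major_diameter=2.0 * a_long,
    )


def run_sweep(
    cfg: ExperimentConfig,
    geom: PlateletGeometry | None = None,
    progress: bool = False,
) -> list[Trajectory]:
    """Run one trajectory per stiffness in ``cfg.K_list``.

    All trajectories share the same shell geometry (so vertex indices align
    across the sweep); per-run seeds are derived from the master seed.
    """
    if geom is None:
        geom = build_ellipsoid_shell(
            cfg.semi_axes, cfg.n_membrane, seed=derive_seed(cfg.seed, "geometry")
        )
    out: list[Trajectory] = []
    # common-random-numbers design: every stiffness level starts from the
    # same fluid realization, so sweep differences are driven by K alone
    seed = derive_seed(cfg.seed, "trajectory")
    for i, K in enumerate(cfg.K_list):
        try:
            out.append(run_trajectory(cfg, K, seed, geom=geom))
        except Exception as exc:  # annotate which stiffness failed
            raise RuntimeError(f"trajectory at K={K} N/m failed: {exc}") from exc
        if progress:
            print(f"  [sweep] K={K:.4f} N/m  Ca*={out[-1].Ca:.4f}  done")
    return out


# ------------------------------------------------------------------- output


def save_trajectories(
    trajs: list[Trajectory], outdir: str | Path, cfg: ExperimentConfig | None = None
) -> Path:
    """Write per-trajectory extended-XYZ + JSON metadata and a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["index,K,Ca,sigma_w,seed,n_snap,n_vertices,xyz,meta"]
    for i, tr in enumerate(trajs):
        stem = f"traj_{i:02d}_K{tr.K:.4f}"
        xyz_path = outdir / f"{stem}.xyz"
        xyz.write_frames(
            xyz_path,
            [tr.positions[k] for k in range(tr.n_snapshots)],
            ["M"] * tr.n_vertices,
            box=(0.0, 0.0, 0.0),
            times=tr.times,
            extra={"K": tr.K, "Ca": tr.Ca},
        )
        meta = {
            "K": tr.K, "K_reduced": tr.K_reduced, "Ca": tr.Ca,
            "sigma_w": tr.sigma_w, "seed": tr.seed, "jeffery_T": tr.jeffery_T,
            "duration": tr.duration, "shear_rate": tr.shear_rate,
            "major_diameter": tr.major_diameter,
            "n_snap": tr.n_snapshots, "n_vertices": tr.n_vertices,
        }
        meta_path = outdir / f"{stem}.json"
        meta_path.write_text(json.dumps(meta, indent=2))
        rows.append(
            f"{i},{tr.K},{tr.Ca},{tr.sigma_w},{tr.seed},{tr.n_snapshots},"
            f"{tr.n_vertices},{xyz_path.name},{meta_path.name}"
        )
    (outdir / "sweep_manifest.csv").write_text("\n".join(rows) + "\n")
    if cfg is not None:
        write_config(cfg, outdir / "config_resolved.yaml")
    return outdir


def load_trajectories(outdir: str | Path) -> list[Trajectory]:
    """Read back a sweep written by :func:`save_trajectories`."""
    outdir = Path(outdir)
    manifest = (outdir / "sweep_manifest.csv").read_text().strip().splitlines()[1:]
    trajs = []
    for row in manifest:
        parts = row.split(",")
        meta = json.loads((outdir / parts[8]).read_text())
        frames = list(xyz.read_frames(outdir / parts[7]))
        positions = np.stack([f["positions"] for f in frames])
        times = np.array([float(f["meta"]["Time"]) for f in frames])
        trajs.append(
            Trajectory(
                K=meta["K"], K_reduced=meta["K_reduced"], Ca=meta["Ca"],
                sigma_w=meta["sigma_w"], times=times, positions=positions,
                seed=meta["seed"], jeffery_T=meta["jeffery_T"],
                duration=meta["duration"], shear_rate=meta["shear_rate"],
                major_diameter=meta["major_diameter"],
            )
        )
    return trajs
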