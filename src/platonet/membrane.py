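"""Membrane-internal forces and fluid-membrane coupling.

The platelet shell carries only harmonic stretch bonds,

    U_harm = sum_bonds K (r - r0)^2,

(note: no 1/2 prefactor), so the restoring force of a bond stretched by
``delta`` has magnitude ``2 K delta``.  The fluid sees the membrane through
a truncated, energy-shifted Lennard-Jones potential plus the usual DPD
dissipative/random exchange, which together enforce an effective no-slip,
no-penetration interface.

These are straightforward NumPy implementations used as the module surface
and in gradient-consistency tests; the production engine evaluates the same
expressions inside the numba kernels of :mod:`platonet.dpd` (their agreement
is asserted in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from platonet.dpd import MEMBRANE, CouplingParams, ParticleState, _pair_noise
from platonet.geometry import PlateletGeometry

__all__ = [
    "MembraneParams",
    "harmonic_bond_forces",
    "harmonic_bond_energy",
    "lj_potential",
    "lj_force",
    "fluid_membrane_forces",
]


@dataclass
class MembraneParams:
    """Membrane constants: bond stiffness, LJ coupling, DPD exchange."""

    K: float                     # bond elastic constant (reduced)
    eps_lj: float
    sigma_lj: float
    lj_cutoff: float
    gamma_hat_m: float
    kBT: float
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.lj_cutoff < self.sigma_lj:
            raise ValueError("LJ cutoff must be >= sigma_lj")

    @property
    def sigma_hat_m(self) -> float:
        """Noise amplitude from sigma_m^2 = 2 gamma_m kBT."""
        return math.sqrt(2.0 * self.gamma_hat_m * self.kBT)

    def coupling(self) -> CouplingParams:
        return CouplingParams(
            eps_lj=self.eps_lj,
            sigma_lj=self.sigma_lj,
            lj_cutoff=self.lj_cutoff,
            gamma_hat_m=self.gamma_hat_m,
            kBT=self.kBT,
        )


# ------------------------------------------------------------ harmonic bonds


def harmonic_bond_energy(
    positions: np.ndarray, geom: PlateletGeometry, K: float
) -> float:
    d = positions[geom.bonds[:, 0]] - positions[geom.bonds[:, 1]]
    r = np.linalg.norm(d, axis=1)
    return float(K * np.sum((r - geom.rest_lengths) ** 2))


def harmonic_bond_forces(
    positions: np.ndarray, geom: PlateletGeometry, K: float
) -> tuple[np.ndarray, float]:
    """Per-vertex harmonic forces and the total bond energy.

    The force on vertex i from bond (i, j) is -2 K (r - r0) e_ij, the exact
    negative gradient of U_harm; forces sum to zero over the shell.
    """
    positions = np.asarray(positions, dtype=float)
    i, j = geom.bonds[:, 0], geom.bonds[:, 1]
    d = positions[i] - positions[j]
    r = np.linalg.norm(d, axis=1)
    stretch = r - geom.rest_lengths
    safe_r = np.where(r > 1e-12, r, 1.0)
    fpair = (-2.0 * K * stretch / safe_r)[:, None] * d
    forces = np.zeros_like(positions)
    np.add.at(forces, i, fpair)
    np.add.at(forces, j, -fpair)
    return forces, float(K * np.sum(stretch**2))


# ------------------------------------------------------------------ LJ pair


def lj_potential(
    r: float | np.ndarray, eps: float, sigma: float, cutoff: float | None = None
) -> float | np.ndarray:
    """Truncated LJ potential, shifted to zero at the cutoff."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6**2 - sr6)
    if cutoff is not None:
        src6 = (sigma / cutoff) ** 6
        u = np.where(r < cutoff, u - 4.0 * eps * (src6**2 - src6), 0.0)
    return float(u) if u.ndim == 0 else u


def lj_force(
    r: float | np.ndarray, eps: float, sigma: float, cutoff: float | None = None
) -> float | np.ndarray:
    """Radial LJ force magnitude -dU/dr (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma / r) ** 6
    f = 24.0 * eps / r * (2.0 * sr6**2 - sr6)
    if cutoff is not None:
        f = np.where(r < cutoff, f, 0.0)
    return float(f) if f.ndim == 0 else f


# ------------------------------------------------- fluid-membrane coupling


def fluid_membrane_forces(
    state: ParticleState,
    params: MembraneParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mixed fluid-membrane force accumulations (reference implementation).

    Conservative part: truncated LJ; dissipative and random parts: DPD forms
    with (gamma_m, sigma_m) and cutoff equal to the fluid r_c (taken as 1 in
    reduced units here).  Uses the same counter-based pair noise as the
    engine, so momentum exchange across the interface sums to zero exactly.
    """
    pos = state.positions
    vel = state.velocities
    mem = state.species == MEMBRANE
    flu = state.species == 0
    idx_m = np.flatnonzero(mem)
    idx_f = np.flatnonzero(flu)
    Lx, _, Lz = state.box
    n = state.n_particles
    Fc = np.zeros((n, 3))
    Fd = np.zeros((n, 3))
    Fr = np.zeros((n, 3))
    r_c = 1.0
    floor = 0.9 * params.sigma_lj
    inv_sqrt_dt = 1.0 / math.sqrt(dt)
    for im in idx_m:
        d = pos[im] - pos[idx_f]
        d[:, 0] -= Lx * np.rint(d[:, 0] / Lx)
        d[:, 2] -= Lz * np.rint(d[:, 2] / Lz)
        r = np.linalg.norm(d, axis=1)
        near = r < max(params.lj_cutoff, r_c)
        for jf, dvec, rij in zip(idx_f[near], d[near], r[near]):
            e = dvec / rij if rij > 1e-12 else np.array([1.0, 0.0, 0.0])
            if rij < params.lj_cutoff:
                f = lj_force(max(rij, floor), params.eps_lj, params.sigma_lj)
                Fc[im] += f * e
                Fc[jf] -= f * e
            if rij < r_c:
                w = 1.0 - rij / r_c
                ev = float(e @ (vel[im] - vel[jf]))
                fd = -params.gamma_hat_m * w * w * ev
                zeta = _pair_noise(state.step_index, int(im), int(jf), state.noise_seed)
                fr = params.sigma_hat_m * w * zeta * inv_sqrt_dt
                Fd[im] += fd * e
                Fd[jf] -= fd * e
                Fr[im] += fr * e
                Fr[jf] -= fr * e
    return Fc, Fd, Fr
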