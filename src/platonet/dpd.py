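"""Mesoscale DPD engine: pairwise forces, integration, walls, diagnostics.

Forces follow the standard DPD decomposition into conservative, dissipative
and random parts,

    F_c = alpha * w_c(r) * e_ij,        w_c(r) = 1 - r/r_c   (r < r_c)
    F_d = -gamma * w_c(r)^2 * (e_ij . v_ij) * e_ij
    F_r = sigma * w_c(r) * zeta_ij * e_ij / sqrt(dt)

with the thermodynamic-consistency constraints w_d = w_r^2 and
sigma^2 = 2 * gamma * kBT.  Membrane-fluid coupling replaces the soft
conservative force by a truncated, shifted Lennard-Jones interaction while
keeping the dissipative/random exchange (see :mod:`platonet.membrane`).

The per-pair noise zeta_ij is generated from a counter-based hash of
(step, min(i,j), max(i,j), seed), which makes it symmetric in (i, j) and
bit-identical between the linked-cell path and the brute-force O(N^2)
reference path regardless of pair iteration order.

Integration uses the Groot-Warren modified velocity-Verlet scheme with
lambda = 1/2: positions are advanced first, forces are then evaluated once
per step at the new positions with half-updated velocities, and the
velocity update completes with the mean of old and new forces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "FluidParams",
    "ParticleState",
    "weight_conservative",
    "pairwise_forces",
    "compute_all_forces",
    "step",
    "kinetic_temperature",
    "velocity_profile",
    "nyquist_max_dt",
    "BlowUpError",
]

# Species tags
FLUID = 0
MEMBRANE = 1
WALL_TOP = 2   # moves at +U ex
WALL_BOT = 3   # moves at -U ex

SPECIES_NAMES = {FLUID: "F", MEMBRANE: "M", WALL_TOP: "Wt", WALL_BOT: "Wb"}


class BlowUpError(RuntimeError):
    """Raised when particle speeds exceed the configured ceiling."""


class NyquistError(ValueError):
    """Raised when the time step cannot resolve the stiffest bond."""


@dataclass
class FluidParams:
    """DPD fluid constants with the consistency constraints built in.

    ``sigma_hat`` is always derived from ``sigma_hat^2 = 2 gamma_hat kBT``;
    ``alpha_hat`` follows the amplitude rule ``75 kBT / (rho_f r_c)`` unless
    given explicitly.
    """

    gamma_hat: float = 4.5
    kBT: float = 1.0
    rho_f: float = 3.0
    r_c: float = 1.0
    m: float = 1.0
    alpha_hat: float | None = None

    def __post_init__(self) -> None:
        if min(self.gamma_hat, self.rho_f, self.r_c, self.m) <= 0:
            raise ValueError("FluidParams fields must be positive")
        if self.kBT < 0:
            raise ValueError("kBT must be non-negative")
        if self.alpha_hat is None:
            self.alpha_hat = 75.0 * self.kBT / (self.rho_f * self.r_c)

    @property
    def sigma_hat(self) -> float:
        return math.sqrt(2.0 * self.gamma_hat * self.kBT)


@dataclass
class CouplingParams:
    """Membrane-fluid interaction constants (LJ + DPD exchange).

    ``sigma_mm`` is the LJ length of the membrane-membrane self-contact
    interaction; it defaults to ``sigma_lj`` but is normally set below the
    smallest non-bonded vertex spacing of the mesh so the rest shell is
    self-force-free.
    """

    eps_lj: float
    sigma_lj: float
    lj_cutoff: float
    gamma_hat_m: float
    kBT: float
    sigma_mm: float | None = None
    mm_cutoff: float | None = None
    eps_mm: float | None = None

    def __post_init__(self) -> None:
        if self.lj_cutoff < self.sigma_lj:
            raise ValueError("LJ cutoff must be >= sigma_lj")
        if self.sigma_mm is None:
            self.sigma_mm = self.sigma_lj
        if self.mm_cutoff is None:
            self.mm_cutoff = 2.5 * self.sigma_mm
        if self.eps_mm is None:
            self.eps_mm = self.eps_lj

    @property
    def sigma_hat_m(self) -> float:
        return math.sqrt(2.0 * self.gamma_hat_m * self.kBT)


@dataclass
class ParticleState:
    """Positions, velocities and species in a periodic sheared box.

    Layout: fluid particles occupy indices ``[0, n_fluid)``, membrane
    vertices ``[n_fluid, n_fluid + n_membrane)``, wall particles the rest.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    mass: np.ndarray
    box: tuple[float, float, float]          # Lx, Ly (gap), Lz
    n_fluid: int
    n_membrane: int
    wall_speed: float = 0.0
    periodic_y: bool = False
    time: float = 0.0
    step_index: int = 0
    noise_seed: int = 0
    bond_exclusions: np.ndarray | None = None   # (n_membrane, max_deg) global ids
    forces: np.ndarray | None = None            # cached total force
    n_capped: int = 0                           # capped-core events (logged)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def membrane_slice(self) -> slice:
        return slice(self.n_fluid, self.n_fluid + self.n_membrane)

    @property
    def mobile(self) -> np.ndarray:
        return self.species < WALL_TOP

    def membrane_positions(self) -> np.ndarray:
        return self.positions[self.membrane_slice].copy()

    def copy(self) -> "ParticleState":
        return ParticleState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            mass=self.mass.copy(),
            box=self.box,
            n_fluid=self.n_fluid,
            n_membrane=self.n_membrane,
            wall_speed=self.wall_speed,
            periodic_y=self.periodic_y,
            time=self.time,
            step_index=self.step_index,
            noise_seed=self.noise_seed,
            bond_exclusions=None if self.bond_exclusions is None
            else self.bond_exclusions.copy(),
            forces=None if self.forces is None else self.forces.copy(),
            n_capped=self.n_capped,
        )


# ------------------------------------------------------------------ weights


def weight_conservative(r: float | np.ndarray, r_c: float) -> float | np.ndarray:
    """Linear DPD weight 1 - r/r_c for r < r_c, zero beyond the cutoff."""
    w = 1.0 - np.asarray(r, dtype=float) / r_c
    out = np.where(np.asarray(r) < r_c, w, 0.0)
    return float(out) if np.isscalar(r) else out


# ------------------------------------------------------- counter-based noise

_C1 = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0xBF58476D1CE4E5B9)
_C3 = np.uint64(0x94D049BB133111EB)
_C4 = np.uint64(0xD6E8FEB86659FD93)
_TWO_M53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _splitmix64(x):
    z = (x + _C1)
    z = (z ^ (z >> np.uint64(30))) * _C2
    z = (z ^ (z >> np.uint64(27))) * _C3
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _pair_noise(step, i, j, seed):
    """Standard normal deviate for pair (i, j) at a given step; zeta_ij = zeta_ji."""
    if i > j:
        i, j = j, i
    x = (np.uint64(seed) * _C2) ^ (np.uint64(step) * _C3) ^ (
        np.uint64(i) * _C1
    ) ^ np.uint64(j)
    h1 = _splitmix64(x)
    h2 = _splitmix64(x ^ _C4)
    u1 = (h1 >> np.uint64(11)) * _TWO_M53
    u2 = (h2 >> np.uint64(11)) * _TWO_M53
    if u1 < 1e-300:
        u1 = 1e-300
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


# ----------------------------------------------------------- pair force core


@njit(cache=True, inline="always")
def _is_excluded(i_mem_row, j, excl):
    for k in range(excl.shape[1]):
        g = excl[i_mem_row, k]
        if g == j:
            return True
        if g < 0:
            return False
    return False


@njit(cache=True)
def _accumulate_pair(
    i, j, dx, dy, dz, r2, vel, species, excl, nf,
    alpha, gamma_f, sigma_f, r_c,
    gamma_m, sigma_m, eps_lj, sig_lj, r_lj, sig_mm, r_mm, eps_mm,
    inv_sqrt_dt, step, seed, Fc, Fd, Fr,
):
    si = species[i]
    sj = species[j]
    if si >= WALL_TOP and sj >= WALL_TOP:
        return 0
    both_membrane = si == MEMBRANE and sj == MEMBRANE
    mixed = (si == MEMBRANE) != (sj == MEMBRANE)

    r = math.sqrt(r2)
    n_cap = 0
    if r < 1e-12:
        # coincident particles: deterministic fallback direction, capped
        ex, ey, ez = 1.0, 0.0, 0.0
        r = 0.0
        n_cap = 1
    else:
        ex, ey, ez = dx / r, dy / r, dz / r

    dvx = vel[i, 0] - vel[j, 0]
    dvy = vel[i, 1] - vel[j, 1]
    dvz = vel[i, 2] - vel[j, 2]
    ev = ex * dvx + ey * dvy + ez * dvz

    if both_membrane:
        if _is_excluded(i - nf, j, excl):
            return 0
        if r < r_mm:
            r_eff = r
            if r_eff < 0.9 * sig_mm:
                r_eff = 0.9 * sig_mm
                n_cap += 1
            sr6 = (sig_mm / r_eff) ** 6
            fmag = 24.0 * eps_mm / r_eff * (2.0 * sr6 * sr6 - sr6)
            Fc[i, 0] += fmag * ex
            Fc[i, 1] += fmag * ey
            Fc[i, 2] += fmag * ez
            Fc[j, 0] -= fmag * ex
            Fc[j, 1] -= fmag * ey
            Fc[j, 2] -= fmag * ez
        return n_cap

    if mixed:
        # conservative: truncated LJ
        if r < r_lj:
            r_eff = r
            if r_eff < 0.9 * sig_lj:
                r_eff = 0.9 * sig_lj
                n_cap += 1
            sr6 = (sig_lj / r_eff) ** 6
            fmag = 24.0 * eps_lj / r_eff * (2.0 * sr6 * sr6 - sr6)
            Fc[i, 0] += fmag * ex
            Fc[i, 1] += fmag * ey
            Fc[i, 2] += fmag * ez
            Fc[j, 0] -= fmag * ex
            Fc[j, 1] -= fmag * ey
            Fc[j, 2] -= fmag * ez
        # dissipative + random DPD exchange
        if r < r_c:
            w = 1.0 - r / r_c
            fd = -gamma_m * w * w * ev
            fr = 0.0
            if sigma_m != 0.0:
                fr = sigma_m * w * _pair_noise(step, i, j, seed) * inv_sqrt_dt
            Fd[i, 0] += fd * ex
            Fd[i, 1] += fd * ey
            Fd[i, 2] += fd * ez
            Fd[j, 0] -= fd * ex
            Fd[j, 1] -= fd * ey
            Fd[j, 2] -= fd * ez
            Fr[i, 0] += fr * ex
            Fr[i, 1] += fr * ey
            Fr[i, 2] += fr * ez
            Fr[j, 0] -= fr * ex
            Fr[j, 1] -= fr * ey
            Fr[j, 2] -= fr * ez
        return n_cap

    # fluid-fluid or fluid-wall: full DPD triplet
    if r < r_c:
        w = 1.0 - r / r_c
        fcm = alpha * w
        fd = -gamma_f * w * w * ev
        fr = 0.0
        if sigma_f != 0.0:
            fr = sigma_f * w * _pair_noise(step, i, j, seed) * inv_sqrt_dt
        Fc[i, 0] += fcm * ex
        Fc[i, 1] += fcm * ey
        Fc[i, 2] += fcm * ez
        Fc[j, 0] -= fcm * ex
        Fc[j, 1] -= fcm * ey
        Fc[j, 2] -= fcm * ez
        Fd[i, 0] += fd * ex
        Fd[i, 1] += fd * ey
        Fd[i, 2] += fd * ez
        Fd[j, 0] -= fd * ex
        Fd[j, 1] -= fd * ey
        Fd[j, 2] -= fd * ez
        Fr[i, 0] += fr * ex
        Fr[i, 1] += fr * ey
        Fr[i, 2] += fr * ez
        Fr[j, 0] -= fr * ex
        Fr[j, 1] -= fr * ey
        Fr[j, 2] -= fr * ez
    return n_cap


@njit(cache=True)
def _forces_bruteforce(
    pos, vel, species, excl, nf, Lx, Lz, Ly_total, periodic_y,
    alpha, gamma_f, sigma_f, r_c, gamma_m, sigma_m,
    eps_lj, sig_lj, r_lj, sig_mm, r_mm, eps_mm, inv_sqrt_dt, step, seed,
):
    n = pos.shape[0]
    Fc = np.zeros((n, 3))
    Fd = np.zeros((n, 3))
    Fr = np.zeros((n, 3))
    rmax = max(r_c, r_lj, r_mm)
    rmax2 = rmax * rmax
    capped = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= Lx * np.rint(dx / Lx)
            dz -= Lz * np.rint(dz / Lz)
            if periodic_y:
                dy -= Ly_total * np.rint(dy / Ly_total)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rmax2:
                continue
            capped += _accumulate_pair(
                i, j, dx, dy, dz, r2, vel, species, excl, nf,
                alpha, gamma_f, sigma_f, r_c, gamma_m, sigma_m,
                eps_lj, sig_lj, r_lj, sig_mm, r_mm, eps_mm,
                inv_sqrt_dt, step, seed, Fc, Fd, Fr,
            )
    return Fc, Fd, Fr, capped


@njit(cache=True)
def _forces_celllist(
    pos, vel, species, excl, nf, Lx, Lz, y_lo, y_hi, periodic_y,
    alpha, gamma_f, sigma_f, r_c, gamma_m, sigma_m,
    eps_lj, sig_lj, r_lj, sig_mm, r_mm, eps_mm, inv_sqrt_dt, step, seed,
):
    n = pos.shape[0]
    Fc = np.zeros((n, 3))
    Fd = np.zeros((n, 3))
    Fr = np.zeros((n, 3))
    rmax = max(r_c, r_lj, r_mm)
    rmax2 = rmax * rmax
    Ly_total = y_hi - y_lo

    ncx = max(1, int(Lx / rmax))
    ncy = max(1, int(Ly_total / rmax))
    ncz = max(1, int(Lz / rmax))
    cx = Lx / ncx
    cy = Ly_total / ncy
    cz = Lz / ncz

    head = -np.ones(ncx * ncy * ncz, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    for p in range(n):
        ix = int((pos[p, 0] % Lx) / cx)
        iy = int((pos[p, 1] - y_lo) / cy)
        iz = int((pos[p, 2] % Lz) / cz)
        if ix >= ncx:
            ix = ncx - 1
        if iy >= ncy:
            iy = ncy - 1
        if iy < 0:
            iy = 0
        if iz >= ncz:
            iz = ncz - 1
        c = (ix * ncy + iy) * ncz + iz
        nxt[p] = head[c]
        head[c] = p

    # half-shell neighbour offsets (13) + in-cell pairs
    offs = np.array(
        [
            [1, 0, 0], [1, 1, 0], [0, 1, 0], [-1, 1, 0],
            [1, 0, 1], [1, 1, 1], [0, 1, 1], [-1, 1, 1],
            [0, 0, 1], [-1, 0, 1], [1, -1, 1], [0, -1, 1], [-1, -1, 1],
        ],
        dtype=np.int64,
    )

    capped = 0
    for ix in range(ncx):
        for iy in range(ncy):
            for iz in range(ncz):
                c = (ix * ncy + iy) * ncz + iz
                i = head[c]
                while i >= 0:
                    # in-cell pairs
                    j = nxt[i]
                    while j >= 0:
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        dx -= Lx * np.rint(dx / Lx)
                        dz -= Lz * np.rint(dz / Lz)
                        if periodic_y:
                            dy -= Ly_total * np.rint(dy / Ly_total)
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < rmax2:
                            capped += _accumulate_pair(
                                i, j, dx, dy, dz, r2, vel, species,
                                excl, nf, alpha, gamma_f, sigma_f, r_c,
                                gamma_m, sigma_m, eps_lj, sig_lj, r_lj,
                                sig_mm, r_mm, eps_mm,
                                inv_sqrt_dt, step, seed, Fc, Fd, Fr,
                            )
                        j = nxt[j]
                    # neighbour-cell pairs
                    for o in range(13):
                        jx = ix + offs[o, 0]
                        jy = iy + offs[o, 1]
                        jz = iz + offs[o, 2]
                        if jy < 0 or jy >= ncy:
                            if not periodic_y:
                                continue
                            jy %= ncy
                        jx %= ncx
                        jz %= ncz
                        cc = (jx * ncy + jy) * ncz + jz
                        j = head[cc]
                        while j >= 0:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= Lx * np.rint(dx / Lx)
                            dz -= Lz * np.rint(dz / Lz)
                            if periodic_y:
                                dy -= (y_hi - y_lo) * np.rint(dy / (y_hi - y_lo))
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rmax2:
                                capped += _accumulate_pair(
                                    i, j, dx, dy, dz, r2, vel, species,
                                    excl, nf, alpha, gamma_f, sigma_f, r_c,
                                    gamma_m, sigma_m, eps_lj, sig_lj, r_lj,
                                    sig_mm, r_mm, eps_mm,
                                    inv_sqrt_dt, step, seed, Fc, Fd, Fr,
                                )
                            j = nxt[j]
                    i = nxt[i]
    return Fc, Fd, Fr, capped


@njit(cache=True)
def _bond_forces_kernel(pos, bonds, rest, K, offset, Lx, Lz):
    """Harmonic bond forces, U = sum_bonds K (r - r0)^2 (no 1/2 prefactor)."""
    n = pos.shape[0]
    F = np.zeros((n, 3))
    energy = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0] + offset
        j = bonds[b, 1] + offset
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= Lx * np.rint(dx / Lx)
        dz -= Lz * np.rint(dz / Lz)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        stretch = r - rest[b]
        energy += K * stretch * stretch
        if r > 1e-12:
            fmag = -2.0 * K * stretch / r
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[i, 2] += fmag * dz
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
            F[j, 2] -= fmag * dz
    return F, energy


# ------------------------------------------------------------- public forces


def _empty_exclusions() -> np.ndarray:
    return -np.ones((1, 1), dtype=np.int64)


def pairwise_forces(
    state: ParticleState,
    params: FluidParams,
    dt: float,
    coupling: CouplingParams | None = None,
    brute_force: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conservative, dissipative and random force accumulations.

    The three components are returned separately; each is pairwise
    antisymmetric so all three sum to zero over a wall-free system.
    ``brute_force=True`` selects the all-pairs O(N^2) reference path, which
    produces identical noise (and therefore identical forces up to summation
    order) as the linked-cell path.
    """
    if coupling is None:
        coupling = CouplingParams(
            eps_lj=params.kBT, sigma_lj=0.5 * params.r_c,
            lj_cutoff=0.5 * params.r_c * 2.5,
            gamma_hat_m=params.gamma_hat, kBT=params.kBT,
        )
    excl = state.bond_exclusions
    if excl is None:
        # one padded row per membrane particle so kernel indexing stays valid
        excl = -np.ones((max(1, state.n_membrane), 1), dtype=np.int64)
    Lx, Ly, Lz = state.box
    if state.periodic_y:
        y_lo, y_hi = -Ly / 2.0, Ly / 2.0
    else:
        wt = _wall_extent(state)
        y_lo, y_hi = -Ly / 2.0 - wt, Ly / 2.0 + wt
    rmax = max(params.r_c, coupling.lj_cutoff, coupling.mm_cutoff)
    args = (
        state.positions, state.velocities, state.species, excl,
        state.n_fluid,
        params.alpha_hat, params.gamma_hat, params.sigma_hat, params.r_c,
        coupling.gamma_hat_m, coupling.sigma_hat_m,
        coupling.eps_lj, coupling.sigma_lj, coupling.lj_cutoff,
        coupling.sigma_mm, coupling.mm_cutoff, coupling.eps_mm,
        1.0 / math.sqrt(dt), state.step_index, state.noise_seed,
    )
    n_cells_min = min(
        int(Lx / rmax), int(Lz / rmax),
        int((y_hi - y_lo) / rmax) if state.periodic_y else 3,
    )
    if brute_force or n_cells_min < 3:
        Fc, Fd, Fr, ncap = _forces_bruteforce(
            state.positions, state.velocities, state.species, excl,
            state.n_fluid, Lx, Lz, y_hi - y_lo, state.periodic_y, *args[5:],
        )
    else:
        Fc, Fd, Fr, ncap = _forces_celllist(
            state.positions, state.velocities, state.species, excl,
            state.n_fluid, Lx, Lz, y_lo, y_hi, state.periodic_y, *args[5:],
        )
    state.n_capped += int(ncap)
    return Fc, Fd, Fr


def _wall_extent(state: ParticleState) -> float:
    """Extent of the wall slabs beyond the gap (0 if no wall particles)."""
    if state.n_fluid + state.n_membrane == state.n_particles:
        return 0.0
    wall_y = state.positions[state.n_fluid + state.n_membrane :, 1]
    return max(0.0, float(np.max(np.abs(wall_y))) - state.box[1] / 2.0) + 1e-9


def compute_all_forces(
    state: ParticleState,
    params: FluidParams,
    dt: float,
    coupling: CouplingParams | None = None,
    bonds: np.ndarray | None = None,
    rest_lengths: np.ndarray | None = None,
    K: float = 0.0,
    brute_force: bool = False,
) -> np.ndarray:
    """Total force array (pairwise DPD/LJ plus harmonic bonds)."""
    Fc, Fd, Fr = pairwise_forces(state, params, dt, coupling, brute_force)
    total = Fc + Fd + Fr
    if bonds is not None and len(bonds) and K > 0.0:
        Fb, _ = _bond_forces_kernel(
            state.positions, bonds, rest_lengths, K, state.n_fluid,
            state.box[0], state.box[2],
        )
        total += Fb
    return total


# ---------------------------------------------------------------- integrator


def nyquist_max_dt(K: float, z_max: int, m: float) -> float:
    """Largest admissible time step for bond stiffness K (reduced units).

    The stiffest normal mode of the spring network has frequency
    f_max = (1/2 pi) sqrt(2 K z_max / m); the sampling condition requires
    dt < 1 / (2 f_max).
    """
    if K <= 0:
        return math.inf
    f_max = math.sqrt(2.0 * K * z_max / m) / (2.0 * math.pi)
    return 1.0 / (2.0 * f_max)


def check_nyquist(dt: float, K: float, z_max: int, m: float) -> None:
    dt_max = nyquist_max_dt(K, z_max, m)
    if dt >= dt_max:
        raise NyquistError(
            f"dt={dt:g} cannot resolve the stiffest bond mode; "
            f"maximum admissible dt is {dt_max:g}"
        )


def step(
    state: ParticleState,
    params: FluidParams,
    dt: float,
    coupling: CouplingParams | None = None,
    bonds: np.ndarray | None = None,
    rest_lengths: np.ndarray | None = None,
    K: float = 0.0,
    velocity_ceiling: float = math.inf,
) -> ParticleState:
    """Advance the state one step (in place) and return it.

    Modified velocity-Verlet (Groot-Warren, lambda = 1/2); periodic wrap in
    x and z, moving walls with bounce-back reflection in y.
    """
    Lx, Ly, Lz = state.box
    mobile = state.mobile
    m = state.mass[:, None]
    if state.forces is None:
        state.forces = compute_all_forces(
            state, params, dt, coupling, bonds, rest_lengths, K
        )
    f_old = state.forces
    acc = f_old / m

    pos = state.positions
    vel = state.velocities
    pos[mobile] += dt * vel[mobile] + 0.5 * dt * dt * acc[mobile]

    # translate walls rigidly
    n_bulk = state.n_fluid + state.n_membrane
    if n_bulk < state.n_particles:
        top = state.species == WALL_TOP
        bot = state.species == WALL_BOT
        pos[top, 0] += state.wall_speed * dt
        pos[bot, 0] -= state.wall_speed * dt

    # periodic wrap
    pos[:, 0] %= Lx
    pos[:, 2] %= Lz
    pos[:, 0][pos[:, 0] >= Lx] = 0.0
    pos[:, 2][pos[:, 2] >= Lz] = 0.0
    if state.periodic_y:
        pos[:, 1] = (pos[:, 1] + Ly / 2.0) % Ly - Ly / 2.0
    else:
        _bounce_back(state, dt)

    # half-updated velocities for the dissipative force evaluation
    v_save = vel.copy()
    vel[mobile] += 0.5 * dt * acc[mobile]
    state.step_index += 1
    f_new = compute_all_forces(state, params, dt, coupling, bonds, rest_lengths, K)
    vel[:] = v_save
    vel[mobile] += 0.5 * dt * (f_old[mobile] + f_new[mobile]) / m[mobile]
    state.forces = f_new
    state.time += dt

    vmax = float(np.max(np.abs(vel[mobile]))) if np.any(mobile) else 0.0
    if not np.isfinite(vmax) or vmax > velocity_ceiling:
        raise BlowUpError(
            f"velocity {vmax:g} exceeded ceiling {velocity_ceiling:g} "
            f"at t={state.time:g} (step {state.step_index})"
        )
    return state


def _bounce_back(state: ParticleState, dt: float) -> None:
    """Reflect mobile particles that penetrated a wall plane."""
    Ly = state.box[1]
    half = Ly / 2.0
    pos, vel = state.positions, state.velocities
    mobile = state.mobile
    over = mobile & (pos[:, 1] > half)
    under = mobile & (pos[:, 1] < -half)
    if np.any(over):
        pos[over, 1] = Ly - pos[over, 1]
        vel[over] = -vel[over]
        vel[over, 0] += 2.0 * state.wall_speed
    if np.any(under):
        pos[under, 1] = -Ly - pos[under, 1]
        vel[under] = -vel[under]
        vel[under, 0] -= 2.0 * state.wall_speed


# --------------------------------------------------------------- diagnostics


def kinetic_temperature(state: ParticleState, n_bins: int = 16) -> float:
    """Streaming-corrected kinetic temperature of the fluid.

    The mean velocity of each y-bin (the local shear streaming field) is
    subtracted before forming m <|v - v_bin|^2> / 3, so a pure shear flow
    with no thermal component reports zero.
    """
    fl = state.species == FLUID
    if np.count_nonzero(fl) < 2:
        raise ValueError("kinetic temperature needs at least 2 fluid particles")
    y = state.positions[fl, 1]
    v = state.velocities[fl]
    m = state.mass[fl]
    bins = np.clip(
        ((y + state.box[1] / 2.0) / state.box[1] * n_bins).astype(int), 0, n_bins - 1
    )
    dv = v.copy()
    for b in range(n_bins):
        sel = bins == b
        if np.any(sel):
            dv[sel] -= v[sel].mean(axis=0)
    return float(np.mean(m * np.sum(dv * dv, axis=1)) / 3.0)


def velocity_profile(
    states: list[ParticleState] | ParticleState, n_bins: int = 20
) -> dict:
    """Time-averaged x-velocity profile of the fluid versus y.

    Returns bin centres, mean v_x per bin, per-bin particle counts and a
    boolean flag for empty bins (left as NaN, never interpolated).
    """
    if isinstance(states, ParticleState):
        states = [states]
    Ly = states[0].box[1]
    edges = np.linspace(-Ly / 2.0, Ly / 2.0, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for st in states:
        fl = st.species == FLUID
        y = st.positions[fl, 1]
        vx = st.velocities[fl, 0]
        idx = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, n_bins - 1)
        np.add.at(sums, idx, vx)
        np.add.at(counts, idx, 1)
    mean = np.full(n_bins, np.nan)
    ok = counts > 0
    mean[ok] = sums[ok] / counts[ok]
    return {
        "y": 0.5 * (edges[:-1] + edges[1:]),
        "v_x": mean,
        "counts": counts,
        "empty": ~ok,
    }


def fit_profile_slope(profile: dict) -> tuple[float, float]:
    """Least-squares slope and R^2 of the (non-empty bins of a) profile."""
    ok = ~profile["empty"]
    y = profile["y"][ok]
    v = profile["v_x"][ok]
    A = np.column_stack([y, np.ones_like(y)])
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    resid = v - A @ coef
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), r2
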