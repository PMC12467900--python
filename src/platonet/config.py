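"""Reduced-unit system and validated experiment configuration.

The engine works in reduced DPD units (cutoff r_c = 1, fluid particle mass
m = 1); SI quantities (wall shear stress in Pa, bond stiffness in N/m, the
16x16x8 um reference box) ride along as metadata used for reporting and as
the physical labels attached to each trajectory.  A :class:`UnitSystem`
records the four base scales and enforces the dimensional relation
``time = length * sqrt(mass / energy)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "UnitSystem",
    "ExperimentConfig",
    "load_config",
    "write_config",
    "derived_shear_rate",
    "derive_seed",
]


class ConfigError(ValueError):
    """Raised when a configuration value fails validation."""


# --------------------------------------------------------------------------- units


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced simulation units and SI.

    Parameters
    ----------
    length_scale:
        Metres per reduced length unit.
    energy_scale:
        Joules per reduced energy unit.
    mass_scale:
        Kilograms per reduced mass unit.

    The time scale is derived, ``time_scale = length_scale *
    sqrt(mass_scale / energy_scale)``, and exposed as an attribute so the
    invariant can be checked rather than trusted.
    """

    length_scale: float
    energy_scale: float
    mass_scale: float
    time_scale: float = 0.0  # derived in __post_init__ when left at 0

    def __post_init__(self) -> None:
        for name in ("length_scale", "energy_scale", "mass_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"UnitSystem.{name} must be positive")
        derived = self.length_scale * math.sqrt(self.mass_scale / self.energy_scale)
        if self.time_scale == 0.0:
            object.__setattr__(self, "time_scale", derived)
        elif not math.isclose(self.time_scale, derived, rel_tol=1e-12):
            raise ConfigError(
                "UnitSystem.time_scale inconsistent with "
                "length*sqrt(mass/energy)"
            )

    # Exponent table: scale factor for a quantity with dimensions
    # length^a * mass^b * time^c  is  L^a M^b T^c.
    _DIMS = {
        "length": (1, 0, 0),
        "mass": (0, 1, 0),
        "time": (0, 0, 1),
        "velocity": (1, 0, -1),
        "energy": (2, 1, -2),
        "force": (1, 1, -2),
        "shear_rate": (0, 0, -1),
        "stress": (-1, 1, -2),
        "viscosity": (-1, 1, -1),
        "stiffness": (0, 1, -2),  # N/m = kg/s^2
        "number_density": (-3, 0, 0),
    }

    def factor(self, dimension: str) -> float:
        """SI units per one reduced unit of the given dimension."""
        a, b, c = self._DIMS[dimension]
        return self.length_scale**a * self.mass_scale**b * self.time_scale**c

    def to_reduced(self, value_si: float, dimension: str) -> float:
        return value_si / self.factor(dimension)

    def to_si(self, value_reduced: float, dimension: str) -> float:
        return value_reduced * self.factor(dimension)


# ---------------------------------------------------------------- configuration

#: Stiffness sweep of the reference study: 0.0003 to 0.0030 N/m in steps
#: of 0.0003 N/m (ten levels).
DEFAULT_K_LIST = tuple(round(0.0003 * i, 6) for i in range(1, 11))


@dataclass
class ExperimentConfig:
    """Validated description of a Couette-flow platelet experiment.

    SI fields label the physical experiment; ``*_reduced`` and geometric
    fields drive the desk-scale engine directly.
    """

    # --- SI metadata -------------------------------------------------------
    sigma_w: float = 50.0          # wall shear stress [Pa]
    mu: float = 3.5e-3             # dynamic viscosity of blood [Pa s]
    box_si: float = 16e-6          # wall spacing L of the reference box [m]
    K_list: tuple[float, ...] = DEFAULT_K_LIST  # bond stiffness sweep [N/m]
    temperature_si: float = 310.0  # reference temperature [K]

    # --- reduced-unit engine parameters -----------------------------------
    Lx: float = 16.0               # box lengths [reduced length]
    Ly: float = 16.0               # wall-normal gap
    Lz: float = 8.0
    rho_f: float = 3.0             # fluid number density
    r_c: float = 1.0               # DPD cutoff
    gamma_hat: float = 12.0        # DPD friction
    kBT: float = 0.0               # reduced temperature (0 = athermal sweep)
    alpha_hat: float | None = 8.0      # conservative amplitude (None = kBT rule)
    shear_rate_reduced: float = 0.25   # imposed gamma_dot = 2U/Ly
    dt: float = 0.025              # time step [reduced time]
    stiffness_scale: float = 4000.0    # reduced stiffness per (N/m)

    # --- membrane ----------------------------------------------------------
    semi_axes: tuple[float, float, float] = (2.0, 2.0, 0.5)
    n_membrane: int = 500
    eps_lj: float = 0.05           # LJ well depth [reduced energy]
    eps_mm: float = 0.01           # membrane self-contact LJ well depth
    sigma_lj: float = 0.2          # LJ length in units of r_c
    lj_cutoff_factor: float = 2.5  # cutoff = factor * sigma_lj
    sigma_mm_factor: float = 0.5   # membrane self-LJ length / min bond rest length
    gamma_hat_m: float = 4.5       # membrane-fluid DPD friction
    membrane_mass: float = 1.0

    # --- walls and run control --------------------------------------------
    wall_thickness: float = 1.0
    wall_density: float = 3.0
    warmup_steps: int = 600        # zero-shear equilibration
    shear_warmup_steps: int = 200  # sheared settling before recording
    n_snap: int = 101
    velocity_ceiling: float = 50.0
    seed: int = 1234

    # --- surrogate training -----------------------------------------------
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    lr_floor: float = 1e-7
    train_fraction: float = 0.9

    def __post_init__(self) -> None:
        self.K_list = tuple(float(k) for k in self.K_list)
        self.semi_axes = tuple(float(a) for a in self.semi_axes)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        def positive(name: str) -> None:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")

        for name in (
            "mu", "box_si", "Lx", "Ly", "Lz", "rho_f", "r_c", "gamma_hat",
            "dt", "stiffness_scale", "n_membrane", "sigma_lj", "eps_lj", "eps_mm",
            "lj_cutoff_factor", "sigma_mm_factor", "gamma_hat_m", "membrane_mass",
            "wall_thickness", "wall_density", "velocity_ceiling",
            "epochs", "batch_size", "learning_rate", "lr_floor",
        ):
            positive(name)
        if not self.K_list:
            raise ConfigError("K_list must be non-empty")
        if any(k <= 0 for k in self.K_list):
            raise ConfigError("K_list entries must be strictly positive")
        if any(b <= a for a, b in zip(self.K_list, self.K_list[1:])):
            raise ConfigError("K_list must be strictly increasing")
        if self.n_snap < 2:
            raise ConfigError(f"n_snap must be >= 2, got {self.n_snap}")
        if len(self.semi_axes) != 3 or any(a <= 0 for a in self.semi_axes):
            raise ConfigError("semi_axes must be three positive numbers")
        if self.kBT < 0:
            raise ConfigError("kBT must be non-negative")
        if self.alpha_hat is not None and self.alpha_hat < 0:
            raise ConfigError("alpha_hat must be non-negative")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.shear_rate_reduced < 0:
            raise ConfigError("shear_rate_reduced must be non-negative")
        if self.warmup_steps < 0 or self.shear_warmup_steps < 0:
            raise ConfigError("warm-up step counts must be non-negative")

    # -- derived quantities -------------------------------------------------
    @property
    def wall_speed(self) -> float:
        """Reduced wall speed U with gamma_dot = 2U/Ly."""
        return self.shear_rate_reduced * self.Ly / 2.0

    @property
    def lj_cutoff(self) -> float:
        return self.lj_cutoff_factor * self.sigma_lj

    @property
    def major_diameter(self) -> float:
        """Rest diameter along the platelet's longest axis [reduced]."""
        return 2.0 * max(self.semi_axes)

    def stiffness_reduced(self, K_si: float) -> float:
        """Map a bond stiffness in N/m to its reduced-unit engine value."""
        return K_si * self.stiffness_scale

    def unit_system(self) -> UnitSystem:
        """Unit mapping implied by the config.

        The length scale pins the engine box to the reference 16 um gap;
        the mass scale is chosen so that the SI shear rate sigma_w/mu maps
        onto the configured reduced shear rate, which fixes the time scale.
        The energy scale then follows from time = length*sqrt(mass/energy).
        """
        length = self.box_si / self.Ly
        gd_si = derived_shear_rate(self)
        if gd_si <= 0 or self.shear_rate_reduced <= 0:
            time = 1e-6  # arbitrary but positive for quiescent configs
        else:
            time = self.shear_rate_reduced / gd_si
        # pick energy so that one reduced energy is kBT_si / kBT_reduced;
        # athermal runs fall back to the bond-energy scale
        kbt_ref = self.kBT if self.kBT > 0 else 1.0
        energy = 1.380649e-23 * self.temperature_si / kbt_ref
        mass = energy * (time / length) ** 2
        return UnitSystem(length_scale=length, energy_scale=energy, mass_scale=mass)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["K_list"] = list(self.K_list)
        d["semi_axes"] = list(self.semi_axes)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment configuration.

    Defaults are filled for absent keys; unknown keys are rejected so typos
    fail loudly rather than silently running the default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return ExperimentConfig.from_dict(data)


def write_config(cfg: ExperimentConfig, path: str | Path) -> Path:
    """Write the resolved configuration next to run outputs (frozen copy)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    else:
        path.write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))
    return path


def derived_shear_rate(cfg: ExperimentConfig) -> float:
    """SI shear rate of the Couette cell, gamma_dot = 2U/L = sigma_w/mu.

    The wall speed follows the linear relation U = sigma_w * L / (2 mu),
    so the nominal shear rate is independent of the gap.
    """
    if cfg.mu <= 0:
        raise ConfigError("viscosity mu must be positive")
    return cfg.sigma_w / cfg.mu


def wall_speed_si(cfg: ExperimentConfig) -> float:
    """SI wall speed U = sigma_w * L / (2 mu)."""
    return cfg.sigma_w * cfg.box_si / (2.0 * cfg.mu)


def derive_seed(master: int, *tags: Any) -> int:
    """Deterministically derive a stage seed (< 2**31) from a master seed.

    Stages are tagged by strings/ints; the fan-out uses numpy's SeedSequence
    so independent stages get statistically independent streams.
    """
    tag_ints = [zlib.crc32(repr(t).encode()) for t in tags]
    ss = np.random.SeedSequence([int(master) % (2**32), *tag_ints])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
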