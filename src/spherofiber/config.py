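"""Simulation parameters in nondimensional units, validation, and unit conversion.

All lengths are measured in units of ``V0**(1/3)`` (one cell diameter scale),
times in units of ``t0`` (set by the damping relation ``K_V V0^{4/3} t0 / mu = 1``)
and energies in units of ``K_V V0**2``.  The default parameter set is the
standard operating point of the embedded-spheroid model; a configuration is an
explicit, serializable run manifest (TOML) so that every run can be reproduced
from its echo.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = [
    "SPHERE_SHAPE_INDEX",
    "ConfigError",
    "SimulationConfig",
    "UnitSystem",
    "load_config",
    "loads_config",
    "dumps_config",
    "save_config",
    "to_physical",
]

#: shape index of a perfect sphere, (36*pi)**(1/3); lower bound for any polyhedron
SPHERE_SHAPE_INDEX = (36.0 * math.pi) ** (1.0 / 3.0)


class ConfigError(ValueError):
    """Raised when a configuration fails to parse or violates an invariant."""


@dataclass(frozen=True)
class UnitSystem:
    """Physical meaning of one simulation unit.

    Defaults: one length unit ``V0**(1/3)`` is about 10 um, one time unit
    ``t0`` about 0.144 s, one force unit about 1 nN.
    """

    length_per_unit: float = 10.0   # um per V0^{1/3}
    time_per_unit: float = 0.144    # s per t0
    force_per_unit: float = 1.0     # nN per simulation force unit

    def __post_init__(self) -> None:
        for name in ("length_per_unit", "time_per_unit", "force_per_unit"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"UnitSystem.{name} must be positive")


def to_physical(value: float, kind: str, units: UnitSystem = UnitSystem()) -> float:
    """Convert a nondimensional quantity to physical units (um, s or nN)."""
    scale = {
        "length": units.length_per_unit,
        "time": units.time_per_unit,
        "force": units.force_per_unit,
    }.get(kind)
    if scale is None:
        raise ConfigError(f"unknown unit kind {kind!r} (expected length|time|force)")
    return value * scale


@dataclass
class SimulationConfig:
    """Every model parameter, nondimensionalized.

    Notes
    -----
    ``d_f`` (fiber diameter) and ``xi`` (pore size) enter no energy term; they
    are retained as metadata describing the physical network the lattice
    emulates.  ``A0`` is a derived quantity, ``A0 = s0 * V0**(2/3)``.
    """

    # time integration
    dt: float = 0.005                    # time step [t0]
    t_f: float = 25000.0                 # total duration [t0]
    t_on: float = 500.0                  # linker contraction onset [t0]
    contraction_interval: float = 5000.0  # rest-length ramp duration [t0]
    # vertex model
    K_V: float = 1.0                     # volume stiffness [energy/volume^2]
    K_A: float = 0.01                    # area stiffness [K_V V0^{2/3}]
    V0: float = 1.0                      # target cell volume [length^3]
    s0: float = 5.2                      # dimensionless target shape index
    Gamma: float = 1.0                   # interfacial tension [K_V V0^{4/3}]
    l_th: float = 0.02                   # reconnection threshold [V0^{1/3}]
    mu: float = 1.0                      # vertex mobility
    kT_eff: float = 1.0e-4               # active fluctuation energy [K_V V0^2]
    # fiber network; the stiffness scale K_S is set by mechanical reciprocity
    # with the spheroid (G_network ~ Gamma/R_s at p ~ 0.8, see docs/methods.md)
    K_S: float = 10.0                    # fiber stretch stiffness [K_V V0^{4/3}]
    K_B: float = 2.25e-3                 # fiber bending stiffness (= 1e-4 K_S l0'(0)^2)
    p: float = 0.8                       # bond occupation probability
    fcc_spacing: float = 1.5             # nearest-neighbor bond length [V0^{1/3}]
    d_f: float = 0.03                    # fiber diameter, metadata only
    xi: float = 1.5                      # pore size, metadata only
    # active linker springs
    K_LS: float = 22.5                   # linker stiffness (= K_S l0'(0)^2)
    l0_init: float = 1.5                 # initial linker rest length [V0^{1/3}]
    l0_final: float = 0.2                # final linker rest length [V0^{1/3}]
    # counts
    N_c: int = 400                       # cells in the spheroid
    N_LS: int = 100                      # active linker springs
    N_f: int = 1000                      # fiber lattice sites (before phantom split)
    N_R: int = 20                        # realizations
    seed: int = 0                        # RNG seed

    @property
    def A0(self) -> float:
        return self.s0 * self.V0 ** (2.0 / 3.0)

    def validate(self) -> "SimulationConfig":
        err = self._first_violation()
        if err is not None:
            raise ConfigError(err)
        return self

    def _first_violation(self) -> Union[str, None]:
        if not self.dt > 0:
            return "dt must be > 0"
        if not (self.t_f > self.t_on >= 0):
            return "t_f must exceed t_on and t_on must be >= 0 (keys t_f, t_on)"
        if not self.contraction_interval > 0:
            return "contraction_interval must be > 0"
        if not (0 < self.p <= 1):
            return "p must lie in (0, 1]"
        if not self.l0_final < self.l0_init:
            return "l0_final must be smaller than l0_init"
        for k in ("K_V", "K_A", "Gamma", "K_S", "K_B", "K_LS", "kT_eff"):
            if getattr(self, k) < 0:
                return f"{k} must be >= 0"
        if not self.V0 > 0:
            return "V0 must be > 0"
        if not self.mu > 0:
            return "mu must be > 0"
        if not self.l_th > 0:
            return "l_th must be > 0"
        if self.s0 < SPHERE_SHAPE_INDEX:
            return (f"s0 must be >= (36*pi)^(1/3) ~ {SPHERE_SHAPE_INDEX:.4f}; "
                    "below the sphere bound no polyhedron can realize A0")
        if not self.fcc_spacing > 0:
            return "fcc_spacing must be > 0"
        for k in ("N_c", "N_LS", "N_f", "N_R"):
            v = getattr(self, k)
            if not isinstance(v, int) or v < 0:
                return f"{k} must be a nonnegative integer"
        if self.N_c < 1:
            return "N_c must be >= 1"
        return None


_FIELDS = {f.name: f for f in dataclasses.fields(SimulationConfig)}
_INT_FIELDS = {"N_c", "N_LS", "N_f", "N_R", "seed"}


def loads_config(text: str) -> SimulationConfig:
    """Parse a TOML document into a validated :class:`SimulationConfig`.

    Absent keys take their defaults; unknown keys are rejected.
    """
    try:
        raw = tomllib.loads(text)
    except tomllib.TOMLDecodeError as e:
        raise ConfigError(f"configuration does not parse as TOML: {e}") from e
    kwargs = {}
    for key, value in raw.items():
        if key not in _FIELDS:
            raise ConfigError(f"unknown configuration key {key!r}")
        if key in _INT_FIELDS:
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"key {key!r} must be an integer, got {value!r}")
            kwargs[key] = int(value)
        else:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"key {key!r} must be a number, got {value!r}")
            kwargs[key] = float(value)
    return SimulationConfig(**kwargs).validate()


def load_config(source: Union[str, Path]) -> SimulationConfig:
    """Load a config from a TOML file path, or from TOML text."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and source.endswith(".toml")):
        text = Path(source).read_text()
    else:
        text = str(source)
    return loads_config(text)


def dumps_config(cfg: SimulationConfig) -> str:
    """Serialize to TOML.  Round-trips exactly through :func:`loads_config`."""
    lines = ["# spherofiber run configuration (nondimensional units)"]
    for f in dataclasses.fields(SimulationConfig):
        v = getattr(cfg, f.name)
        if f.name in _INT_FIELDS:
            lines.append(f"{f.name} = {int(v)}")
        else:
            lines.append(f"{f.name} = {float(v)!r}")
    return "\n".join(lines) + "\n"


def save_config(cfg: SimulationConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(dumps_config(cfg))
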