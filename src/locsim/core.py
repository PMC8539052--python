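"""Core domain types shared by every module.

Conventions
-----------
* Right-handed Cartesian coordinates, ``z`` up, with the bottom substrate
  plane at ``z = 0``.
* Vectors are plain ``numpy`` arrays of shape ``(3,)`` (or ``(n, 3)`` when
  batched); diagonal rank-2 tensors such as the diffusion tensor are stored
  as their three diagonal components, shape ``(3,)`` / ``(n, 3)``.
* All stored quantities are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .errors import DomainError

__all__ = [
    "Medium",
    "ParticleState",
    "TimeGrid",
    "mass_from_density",
    "sphere_volume",
    "as_vec3",
]


def as_vec3(x) -> np.ndarray:
    """Coerce ``x`` to a float array of shape ``(3,)`` and check finiteness."""
    v = np.asarray(x, dtype=float).reshape(3)
    if not np.all(np.isfinite(v)):
        raise DomainError(f"non-finite vector component in {x!r}")
    return v


def sphere_volume(ro: float) -> float:
    """Volume of a sphere of radius ``ro`` (m^3)."""
    if ro <= 0:
        raise DomainError(f"radius must be positive, got {ro}")
    return 4.0 / 3.0 * np.pi * ro**3


def mass_from_density(ro: float, rho: float) -> float:
    """Mass (kg) of a homogeneous sphere of radius ``ro`` (m) and density
    ``rho`` (kg/m^3)."""
    if rho <= 0:
        raise DomainError(f"density must be positive, got {rho}")
    return sphere_volume(ro) * rho


@dataclass(frozen=True)
class Medium:
    """Suspension fluid properties.

    Parameters
    ----------
    eta : dynamic viscosity, Pa s.
    T : absolute temperature, K.
    eps_m : relative permittivity (dimensionless), >= 1.
    sigma_m : electrical conductivity, S/m.
    rho_f : density, kg/m^3 — optional, only needed for buoyancy.
    """

    eta: float
    T: float
    eps_m: float = 80.0
    sigma_m: float = 0.0
    rho_f: float | None = None

    def __post_init__(self):
        if self.eta <= 0:
            raise DomainError(f"viscosity must be positive, got {self.eta}")
        if self.T <= 0:
            raise DomainError(f"temperature must be positive, got {self.T}")
        if self.eps_m < 1:
            raise DomainError(f"relative permittivity must be >= 1, got {self.eps_m}")
        if self.sigma_m < 0:
            raise DomainError(f"conductivity must be >= 0, got {self.sigma_m}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B T, J."""
        return KB * self.T


@dataclass
class ParticleState:
    """State and material response of one spherical particle.

    ``dielectric`` is either a fixed real Clausius–Mossotti value (float) or
    a :class:`~locsim.dielectrics.ShellSpec` evaluated at the drive frequency
    when a DEP force field is configured.
    """

    id: int
    ro: float
    m: float
    r: np.ndarray = field(default_factory=lambda: np.zeros(3))
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dielectric: object | None = None

    def __post_init__(self):
        if self.ro <= 0:
            raise DomainError(f"particle radius must be positive, got {self.ro}")
        if self.m <= 0:
            raise DomainError(f"particle mass must be positive, got {self.m}")
        self.r = as_vec3(self.r)
        self.v = as_vec3(self.v)

    @classmethod
    def from_density(cls, id: int, ro: float, rho: float, **kw) -> "ParticleState":
        return cls(id=id, ro=ro, m=mass_from_density(ro, rho), **kw)

    @property
    def volume(self) -> float:
        """Particle volume (m^3), used by volume-scaled force models."""
        return sphere_volume(self.ro)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid t_i = i*dt, i = 0..n_steps."""

    dt: float
    n_steps: int

    def __post_init__(self):
        if self.dt <= 0:
            raise DomainError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 1:
            raise DomainError(f"n_steps must be >= 1, got {self.n_steps}")

    @classmethod
    def from_duration(cls, dt: float, t_end: float) -> "TimeGrid":
        if dt <= 0 or t_end < dt:
            raise DomainError(f"need 0 < dt <= t_end, got dt={dt}, t_end={t_end}")
        return cls(dt=dt, n_steps=int(round(t_end / dt)))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt
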