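"""External force fields: Gaussian optical trap, DEP, gravity/buoyancy.

Every force model implements ``force(r, t, particles) -> (n, 3)`` where
``r`` is an ``(n, 3)`` position array and ``particles`` a
:class:`ParticleArrays` bundle of per-particle properties.  The engine's
external force is the vector sum over the configured fields; fields are
time-gated by wrapping them in :class:`TimeGated`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import EPS0, G
from .core import Medium
from .dielectrics import (
    ShellSpec,
    cm_factor,
    medium_complex_permittivity,
    multishell_effective_permittivity,
)
from .errors import ConfigurationError, DomainError

__all__ = [
    "ParticleArrays",
    "GaussianTrap",
    "TimeGated",
    "DEPForce",
    "GravityBuoyancy",
    "resolve_re_cm",
    "sum_forces",
]


@dataclass
class ParticleArrays:
    """Per-particle property arrays shared with force models.

    radius (m), mass (kg), volume (m^3), rho (kg/m^3), and the real
    Clausius–Mossotti value ``re_cm`` (resolved once at the drive
    frequency for shelled particles).
    """

    radius: np.ndarray
    mass: np.ndarray
    volume: np.ndarray
    re_cm: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.radius)

    @property
    def rho(self) -> np.ndarray:
        return self.mass / self.volume


def resolve_re_cm(dielectric, medium: Medium, f: float) -> float:
    """Real CM value of a particle: a float passes through, a
    :class:`ShellSpec` is homogenized at the drive frequency ``f``."""
    if isinstance(dielectric, ShellSpec):
        eps_p = multishell_effective_permittivity(dielectric, f)
        return cm_factor(eps_p, medium_complex_permittivity(medium, f)).real
    if dielectric is None:
        raise ConfigurationError("particle has no dielectric model but a DEP field is configured")
    return float(dielectric)


class GaussianTrap:
    """Conservative optical trap from a volume-scaled Gaussian potential well.

    ``u(r) = -(4/3) pi ro^3 * Ad * exp(-|r - c|^2 / w^2)`` with well depth
    volume density ``Ad`` (J/m^3) and width ``w`` (m).  The force
    ``F = -grad u`` is radial and points toward the centre everywhere; its
    magnitude peaks at radial distance ``w/sqrt(2)``.
    """

    def __init__(self, ad: float, w: float, center=(0.0, 0.0, 0.0)):
        if w <= 0:
            raise DomainError(f"trap width must be positive, got {w}")
        self.ad = float(ad)
        self.w = float(w)
        self.center = np.asarray(center, dtype=float).reshape(3)

    def potential(self, r, particles: ParticleArrays):
        r = np.asarray(r, dtype=float)
        d2 = np.sum((r - self.center) ** 2, axis=-1)
        return -particles.volume * self.ad * np.exp(-d2 / self.w**2)

    def force(self, r, t, particles: ParticleArrays):
        r = np.asarray(r, dtype=float)
        d = r - self.center
        d2 = np.sum(d**2, axis=-1, keepdims=True)
        prefac = particles.volume[..., None] * self.ad * 2.0 / self.w**2
        return -prefac * d * np.exp(-d2 / self.w**2)


class TimeGated:
    """Gate a base force field to the open interval ``t_on < t < t_off``."""

    def __init__(self, base, t_on: float, t_off: float):
        if not t_on < t_off:
            raise DomainError(f"need t_on < t_off, got {t_on}, {t_off}")
        self.base = base
        self.t_on = float(t_on)
        self.t_off = float(t_off)

    def force(self, r, t, particles: ParticleArrays):
        if self.t_on < t < self.t_off:
            return self.base.force(r, t, particles)
        return np.zeros(np.asarray(r, dtype=float).shape)


class DEPForce:
    """Time-averaged dielectrophoretic force
    ``F = 2 pi eps0 eps_m ro^3 Re(CM) grad|E|^2``.

    ``field`` supplies ``gradient(r)`` of ``|E|^2`` (grid or analytic);
    per-particle ``Re(CM)`` comes from ``particles.re_cm``.
    """

    def __init__(self, field, medium: Medium, frequency: float):
        if frequency <= 0:
            raise DomainError(f"drive frequency must be positive, got {frequency}")
        self.field = field
        self.medium = medium
        self.frequency = float(frequency)

    def force(self, r, t, particles: ParticleArrays):
        if particles.re_cm is None:
            raise ConfigurationError("particles carry no Re(CM) values for the DEP force")
        grad = self.field.gradient(np.asarray(r, dtype=float))
        pref = 2.0 * np.pi * EPS0 * self.medium.eps_m * particles.radius**3 * particles.re_cm
        return pref[..., None] * grad


class GravityBuoyancy:
    """Net gravity minus buoyancy, ``(4/3) pi ro^3 (rho_p - rho_f) g`` along -z."""

    def __init__(self, medium: Medium):
        if medium.rho_f is None:
            raise ConfigurationError("gravity/buoyancy needs the medium density rho_f")
        self.rho_f = float(medium.rho_f)

    def force(self, r, t, particles: ParticleArrays):
        fz = -particles.volume * (particles.rho - self.rho_f) * G
        out = np.zeros(np.asarray(r, dtype=float).shape)
        out[..., 2] = fz
        return out


def sum_forces(fields, r, t, particles: ParticleArrays):
    """Vector sum of all configured force fields at positions ``r``."""
    total = np.zeros(np.asarray(r, dtype=float).shape)
    for fld in fields:
        total = total + fld.force(r, t, particles)
    return total
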