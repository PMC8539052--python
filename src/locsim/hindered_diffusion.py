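"""Position-dependent diffusion near a plane no-slip wall.

A sphere of radius ``ro`` diffusing at centre height ``z`` above a solid
surface at ``z = 0`` experiences hindered diffusion: the free Stokes–Einstein
coefficient ``D0 = kB*T / (6*pi*eta*ro)`` is multiplied by direction-dependent
correction factors ``H_par`` (motion parallel to the wall, Faxén's series)
and ``H_perp`` (motion normal to the wall, a Padé form of Brenner's result).
Both corrections lie in (0, 1], increase with height, and tend to 1 far from
the wall.  The resulting diffusion tensor is diagonal with lateral isotropy:
``D = D0 * diag(H_par, H_par, H_perp)``.

Only the bottom ``z = 0`` surface contributes hindrance; side walls affect
collisions only.  During a prediction step a particle may transiently sit
below contact (``z < ro``); the corrections are evaluated at the clamped
height ``max(z, ro)`` so they stay meaningful there.
"""

from __future__ import annotations

import numpy as np

from .constants import KB
from .core import Medium, ParticleState
from .errors import DomainError

__all__ = [
    "free_diffusion_coefficient",
    "wall_correction_parallel",
    "wall_correction_perpendicular",
    "diffusion_tensor",
]


def free_diffusion_coefficient(ro, medium: Medium):
    """Stokes–Einstein free-space diffusivity kB*T/(6*pi*eta*ro), m^2/s."""
    ro = np.asarray(ro, dtype=float)
    if np.any(ro <= 0):
        raise DomainError("particle radius must be positive")
    return KB * medium.T / (6.0 * np.pi * medium.eta * ro)


def _clamped_ratio(z, ro, clamp: bool):
    z = np.asarray(z, dtype=float)
    ro = np.asarray(ro, dtype=float)
    if np.any(ro <= 0):
        raise DomainError("particle radius must be positive")
    if clamp:
        z = np.maximum(z, ro)
    elif np.any(z < ro):
        raise DomainError("centre height z must be >= particle radius ro")
    return ro / z


def wall_correction_parallel(z, ro, *, clamp: bool = True):
    """Hindrance factor for diffusion parallel to the wall.

    Faxén's truncated series in u = ro/z:
    ``1 - (9/16)u + (1/8)u^3 - (45/256)u^4 - (1/16)u^5``.
    """
    u = _clamped_ratio(z, ro, clamp)
    return (
        1.0
        - 9.0 / 16.0 * u
        + 1.0 / 8.0 * u**3
        - 45.0 / 256.0 * u**4
        - 1.0 / 16.0 * u**5
    )


def wall_correction_perpendicular(z, ro, *, clamp: bool = True):
    """Hindrance factor for diffusion normal to the wall:
    ``(6 z^2 + 2 ro z) / (6 z^2 + 9 ro z + 2 ro^2)``."""
    u = _clamped_ratio(z, ro, clamp)
    # written in terms of u = ro/z to share the clamping path
    return (6.0 + 2.0 * u) / (6.0 + 9.0 * u + 2.0 * u**2)


def diffusion_tensor(z, ro, medium: Medium, *, clamp: bool = True):
    """Diagonal diffusion tensor components ``(Dxx, Dyy, Dzz)`` at centre
    height ``z`` above the floor.

    Accepts scalars or arrays; returns shape ``(..., 3)`` with
    ``Dxx = Dyy = D0*H_par`` and ``Dzz = D0*H_perp``.
    """
    d0 = free_diffusion_coefficient(ro, medium)
    h_par = wall_correction_parallel(z, ro, clamp=clamp)
    h_perp = wall_correction_perpendicular(z, ro, clamp=clamp)
    return np.stack([d0 * h_par, d0 * h_par, d0 * h_perp], axis=-1)


def particle_diffusion_tensor(particle: ParticleState, medium: Medium):
    """Convenience wrapper evaluating :func:`diffusion_tensor` at the
    particle's current height."""
    return diffusion_tensor(particle.r[2], particle.ro, medium)
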