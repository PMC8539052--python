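"""Discretized Langevin velocity/position update.

The underdamped Langevin equation with position-dependent diagonal diffusion
is discretized with an Euler–Maruyama step in which the drag term is
implicit (it uses the new velocity), giving the per-component update

    v_{i+1} = L/(1+L) * v_i
            + 1/(1+L) * ( vf + sqrt(2/dt) * sqrt(D) * w + D * F / (kB*T) )

with the dimensionless inertia number ``L = m*D/(kB*T*dt)``.  The implicit
drag makes the scheme unconditionally stable: with no forcing the velocity
decays geometrically for any ``dt``.  The noise prefactor ``sqrt(2/dt)`` is
the unique choice for which the overdamped limit ``L -> 0`` reproduces the
standard Brownian-dynamics displacement statistics: mean drift
``vf*dt + D*F*dt/(kB*T)`` and per-axis variance ``2*D*dt`` (the
Ermak–McCammon position-Langevin step), i.e. fluctuation–dissipation holds
against the Stokes drag ``kB*T/D``.

Positions then advance with the Euler–Cromer rule ``r_{i+1} = r_i +
v_{i+1}*dt``, which uses the freshly updated velocity.

All operations are array-wide over particles: inputs of shape ``(n, 3)``
update every particle in one vectorized pass.
"""

from __future__ import annotations

import numpy as np

from .constants import KB
from .errors import DomainError

__all__ = [
    "lambda_tensor",
    "velocity_update",
    "position_update",
    "draw_noise",
    "spawn_particle_streams",
]


def lambda_tensor(m, D, T, dt):
    """Dimensionless inertia tensor components ``m*D/(kB*T*dt)``.

    ``m`` broadcasts against the diagonal diffusion components ``D``
    (shape ``(..., 3)``); ``m = 0`` gives the overdamped limit exactly.
    """
    if dt <= 0:
        raise DomainError(f"dt must be positive, got {dt}")
    if T <= 0:
        raise DomainError(f"temperature must be positive, got {T}")
    m = np.asarray(m, dtype=float)
    return m[..., None] * np.asarray(D, dtype=float) / (KB * T * dt) if m.ndim else m * np.asarray(D, dtype=float) / (KB * T * dt)


def velocity_update(v, vf, F, D, m, T, dt, w):
    """One implicit Euler–Maruyama velocity step (vectorized over particles).

    Parameters
    ----------
    v, vf, F, w : arrays of shape ``(..., 3)``
        Current velocity, fluid velocity, external force, and standard
        normal draws.
    D : array of shape ``(..., 3)``
        Diagonal diffusion tensor components, m^2/s (all positive).
    m : scalar or array of shape ``(...,)``
        Particle mass, kg.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise DomainError("diffusion tensor components must be positive")
    lam = lambda_tensor(m, D, T, dt)
    kick = np.sqrt(2.0 / dt) * np.sqrt(D) * np.asarray(w, dtype=float)
    drift = D * np.asarray(F, dtype=float) / (KB * T)
    return (lam * np.asarray(v, dtype=float) + np.asarray(vf, dtype=float) + kick + drift) / (1.0 + lam)


def position_update(r, v_next, dt):
    """Euler–Cromer position step ``r + v_{i+1}*dt``."""
    if dt <= 0:
        raise DomainError(f"dt must be positive, got {dt}")
    return np.asarray(r, dtype=float) + np.asarray(v_next, dtype=float) * dt


def spawn_particle_streams(seed: int, n_particles: int) -> list[np.random.Generator]:
    """Independent per-particle generators derived from one master seed.

    Each particle owns a substream, so the noise a particle sees depends
    only on the master seed and its index — adding diagnostics or more
    particles never shifts another particle's sequence.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n_particles)]


def draw_noise(streams, n_particles: int | None = None) -> np.ndarray:
    """Draw one standard-normal 3-vector per particle, shape ``(n, 3)``.

    ``streams`` is either the list from :func:`spawn_particle_streams`
    (one independent draw per particle) or a single ``numpy`` Generator
    (``n_particles`` then selects the count).
    """
    if isinstance(streams, np.random.Generator):
        if n_particles is None:
            raise DomainError("n_particles required with a single generator")
        return streams.standard_normal((n_particles, 3))
    out = np.empty((len(streams), 3))
    for k, g in enumerate(streams):
        out[k] = g.standard_normal(3)
    return out
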