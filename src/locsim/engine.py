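"""Per-step simulation pipeline and trajectory logging.

Each time step executes, batched over all particles:

1. draw one standard-normal 3-vector per particle (per-particle substreams
   of the master seed),
2. evaluate the hindered diffusion tensor at the pre-step heights,
3. Langevin velocity update (implicit drag) and Euler–Cromer position
   prediction,
4. detect particle–particle and particle–wall collisions on the predicted
   positions,
5. resolve collisions and re-advance affected particles from their
   pre-step positions,
6. commit and (at the configured cadence) log.

Runs are bit-reproducible for a fixed configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import collisions, hindered_diffusion, integrator
from .constants import KB
from .core import Medium, ParticleState, TimeGrid
from .errors import ConfigurationError, NumericalFailureError
from .forces import ParticleArrays, resolve_re_cm, sum_forces

__all__ = ["SimulationConfig", "TrajectoryLog", "initialize", "run", "msd"]

#: Log every step for runs up to this many particle-steps, else decimate.
_FULL_LOG_LIMIT = 200_000


@dataclass
class SimulationConfig:
    """Everything a run needs.

    ``particles`` is a list of :class:`ParticleState` templates (positions
    may be overwritten by ``init_box`` sampling).  ``init_box`` is
    ``((x0, x1), (y0, y1), (z0, z1))`` in metres for uniform initial
    positions; leave ``None`` to take particle positions verbatim.
    ``dep_frequency`` is the drive frequency used to resolve shelled
    dielectric models to Re(CM) values at startup.
    """

    dt: float
    t_end: float
    seed: int
    particles: list
    medium: Medium
    forces: list = dc_field(default_factory=list)
    flow: object | None = None
    walls: object | None = None
    init_box: tuple | None = None
    thermal_velocities: bool = False
    log_every: int | None = None
    dep_frequency: float | None = None
    hindered: bool = True

    def time_grid(self) -> TimeGrid:
        return TimeGrid.from_duration(self.dt, self.t_end)


@dataclass
class TrajectoryLog:
    """Logged times (s) plus positions/velocities, SI, shapes
    ``(n_log,)``, ``(n_log, n_particles, 3)``."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Normative tabular layout: one row per particle per logged step,
        columns ``t_s, particle_id, x_um, y_um, z_um, vx_um_s, vy_um_s,
        vz_um_s``."""
        n_log, n_p, _ = self.positions.shape
        return pd.DataFrame(
            {
                "t_s": np.repeat(self.times, n_p),
                "particle_id": np.tile(np.arange(n_p), n_log),
                "x_um": self.positions[..., 0].ravel() * 1e6,
                "y_um": self.positions[..., 1].ravel() * 1e6,
                "z_um": self.positions[..., 2].ravel() * 1e6,
                "vx_um_s": self.velocities[..., 0].ravel() * 1e6,
                "vy_um_s": self.velocities[..., 1].ravel() * 1e6,
                "vz_um_s": self.velocities[..., 2].ravel() * 1e6,
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("t_s", data=self.times)
            fh.create_dataset("position_um", data=self.positions * 1e6)
            fh.create_dataset("velocity_um_s", data=self.velocities * 1e6)
            fh.attrs["columns"] = json.dumps(["t_s", "position_um", "velocity_um_s"])

    def write_meta(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)


def initialize(config: SimulationConfig, rng: np.random.Generator):
    """Initial position/velocity arrays.

    Uniform-box positions are rejection-sampled until no two particles
    overlap (at most 10^4 attempts per particle); explicit positions pass
    through verbatim.  Velocities default to zero; with
    ``thermal_velocities`` they are Maxwell–Boltzmann draws.
    """
    n = len(config.particles)
    radius = np.array([p.ro for p in config.particles])
    pos = np.stack([p.r for p in config.particles]).astype(float)
    if config.init_box is not None:
        lo = np.array([b[0] for b in config.init_box])
        hi = np.array([b[1] for b in config.init_box])
        for k in range(n):
            for attempt in range(10_000):
                cand = rng.uniform(lo, hi)
                if k == 0 or np.all(
                    np.linalg.norm(pos[:k] - cand, axis=1) > radius[:k] + radius[k]
                ):
                    pos[k] = cand
                    break
            else:
                raise ConfigurationError(
                    f"could not place particle {k} without overlap in the initial box"
                )
    vel = np.stack([p.v for p in config.particles]).astype(float)
    if config.thermal_velocities:
        mass = np.array([p.m for p in config.particles])
        sigma = np.sqrt(KB * config.medium.T / mass)
        vel = rng.standard_normal((n, 3)) * sigma[:, None]
    return pos, vel


def _particle_arrays(config: SimulationConfig) -> ParticleArrays:
    radius = np.array([p.ro for p in config.particles])
    mass = np.array([p.m for p in config.particles])
    volume = np.array([p.volume for p in config.particles])
    re_cm = None
    if any(p.dielectric is not None for p in config.particles):
        if config.dep_frequency is None:
            raise ConfigurationError("dep_frequency is required to resolve dielectric models")
        re_cm = np.array(
            [
                resolve_re_cm(p.dielectric, config.medium, config.dep_frequency)
                if p.dielectric is not None
                else 0.0
                for p in config.particles
            ]
        )
    return ParticleArrays(radius=radius, mass=mass, volume=volume, re_cm=re_cm)


def step(pos, vel, t, dt, config: SimulationConfig, particles: ParticleArrays, noise):
    """Advance one time step; returns committed ``(pos, vel)``."""
    medium = config.medium
    if config.hindered:
        D = hindered_diffusion.diffusion_tensor(pos[:, 2], particles.radius, medium)
    else:
        d0 = hindered_diffusion.free_diffusion_coefficient(particles.radius, medium)
        D = np.repeat(d0[:, None], 3, axis=1)
    vf = config.flow.velocity(pos, t) if config.flow is not None else np.zeros_like(pos)
    F = sum_forces(config.forces, pos, t, particles)
    v_pred = integrator.velocity_update(vel, vf, F, D, particles.mass, medium.T, dt, noise)
    r_pred = integrator.position_update(pos, v_pred, dt)
    events = collisions.detect_collisions(r_pred, particles.radius, config.walls)
    r_new, v_new = collisions.apply_adjustments(pos, r_pred, v_pred, particles.mass, events, dt)
    return r_new, v_new


def run(config: SimulationConfig) -> TrajectoryLog:
    """Execute the full pipeline over the configured time grid."""
    grid = config.time_grid()
    n = len(config.particles)
    streams = integrator.spawn_particle_streams(config.seed, n + 1)
    init_rng = streams[-1]
    particle_streams = streams[:n]
    pos, vel = initialize(config, init_rng)
    particles = _particle_arrays(config)

    if config.log_every is not None:
        log_every = max(1, int(config.log_every))
    else:
        log_every = 1 if n * grid.n_steps <= _FULL_LOG_LIMIT else int(
            np.ceil(n * grid.n_steps / _FULL_LOG_LIMIT)
        )
    logged = [0] + [i for i in range(1, grid.n_steps + 1) if i % log_every == 0]
    if logged[-1] != grid.n_steps:
        logged.append(grid.n_steps)
    times = np.array([grid.dt * i for i in logged])
    positions = np.empty((len(logged), n, 3))
    velocities = np.empty((len(logged), n, 3))
    positions[0], velocities[0] = pos, vel

    cursor = 1
    for i in range(grid.n_steps):
        noise = integrator.draw_noise(particle_streams)
        pos, vel = step(pos, vel, grid.dt * i, grid.dt, config, particles, noise)
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(vel))):
            raise NumericalFailureError(f"non-finite state at step {i + 1}", step=i + 1)
        if cursor < len(logged) and (i + 1) == logged[cursor]:
            positions[cursor], velocities[cursor] = pos, vel
            cursor += 1

    return TrajectoryLog(
        times=times,
        positions=positions,
        velocities=velocities,
        meta={
            "seed": config.seed,
            "dt_s": config.dt,
            "t_end_s": config.t_end,
            "n_particles": n,
            "log_every": log_every,
        },
    )


def msd(log: TrajectoryLog, particle: int, axis: int | None = None, lags=None):
    """Mean squared displacement versus lag time for one particle.

    ``axis`` selects a Cartesian component (None = full 3D MSD); ``lags``
    is an iterable of integer lag indices (default: 20 log-spaced lags up
    to a quarter of the trajectory).  Returns ``(lag_times, msd_values)``.
    """
    traj = log.positions[:, particle, :]
    if axis is not None:
        traj = traj[:, axis : axis + 1]
    n = traj.shape[0]
    if n < 2:
        raise ConfigurationError("msd needs at least two logged steps")
    if lags is None:
        lags = np.unique(np.round(np.logspace(0, np.log10(max(n // 4, 1)), 20)).astype(int))
        lags = lags[lags >= 1]
    lag_t = []
    vals = []
    for lag in lags:
        d = traj[lag:] - traj[:-lag]
        vals.append(np.mean(np.sum(d**2, axis=1)))
        lag_t.append(log.times[lag] - log.times[0])
    return np.asarray(lag_t), np.asarray(vals)
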