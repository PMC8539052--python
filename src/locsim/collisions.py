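"""Hard-sphere elastic collision detection and resolution.

Particle–particle contacts are resolved by decomposing the velocities along
the contact normal ``n = (rp - rq)/|rp - rq|``: the normal components are
transformed by the one-dimensional elastic-collision formula (momentum and
kinetic energy conserved), the tangential components are untouched.
Particle–wall contacts reflect the velocity about the wall plane,
``v' = v - 2 (v.n) n`` (walls are effectively infinitely massive).

Detection happens on the *predicted* (post-Langevin) positions; adjusted
velocities then re-advance the particle from its *pre-step* position, so a
particle that would have tunnelled into a wall or a neighbour instead moves
along the corrected direction for the whole step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "CollisionEvent",
    "collision_normal",
    "resolve_particle_collision",
    "resolve_wall_collision",
    "detect_collisions",
    "apply_adjustments",
]

logger = logging.getLogger(__name__)

_UNIT_TOL = 1e-9

#: Fallback contact normal for the probability-zero case of coincident
#: centres (+z, pointing from q to p by convention).
_FALLBACK_NORMAL = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class CollisionEvent:
    """One detected contact.

    ``kind`` is ``"pp"`` (particle–particle, ``q`` is the partner index) or
    ``"pw"`` (particle–wall, ``q`` is the wall id).  ``n_hat`` is the unit
    contact normal: for "pp" it points from q to p; for "pw" it is the
    wall's normal on the fluid side of the particle.
    """

    kind: str
    p: int
    q: int
    n_hat: np.ndarray


def _check_unit(n_hat) -> np.ndarray:
    n = np.asarray(n_hat, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > _UNIT_TOL:
        raise DomainError(f"normal must be unit length, got |n| = {np.linalg.norm(n)}")
    return n


def collision_normal(rp, rq) -> np.ndarray:
    """Unit normal from particle q to particle p."""
    d = np.asarray(rp, dtype=float) - np.asarray(rq, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0.0:
        logger.warning("coincident particle centres; using +z fallback normal")
        return _FALLBACK_NORMAL.copy()
    return d / norm


def resolve_particle_collision(vp, vq, mp, mq, n_hat):
    """Elastic two-body resolution; returns the post-collision pair.

    Normal components follow the 1D elastic-collision formula

        vp_n' = ((mp - mq) vp_n + 2 mq vq_n) / (mp + mq)

    (and symmetrically for q); tangential components are unchanged, so the
    whole update is ``v' = v - 2 m_other/(mp+mq) * ((vp - vq).n) n`` applied
    with opposite signs to the two bodies.
    """
    if mp <= 0 or mq <= 0:
        raise DomainError("masses must be positive")
    n = _check_unit(n_hat)
    vp = np.asarray(vp, dtype=float)
    vq = np.asarray(vq, dtype=float)
    closing = float(np.dot(vp - vq, n))
    vp_new = vp - (2.0 * mq / (mp + mq)) * closing * n
    vq_new = vq + (2.0 * mp / (mp + mq)) * closing * n
    return vp_new, vq_new


def resolve_wall_collision(v, n_wall):
    """Specular reflection ``v - 2 (v.n) n`` off an infinitely massive wall."""
    n = _check_unit(n_wall)
    v = np.asarray(v, dtype=float)
    return v - 2.0 * np.dot(v, n) * n


def detect_collisions(positions, radii, walls=None) -> list[CollisionEvent]:
    """Flag overlapping pairs and wall penetrations at the given positions.

    A pair (p, q) collides iff ``|rp - rq| < ro_p + ro_q``; a particle
    collides with a wall iff its signed distance to the wall is below its
    radius.  Events are ordered particle–particle first, ascending (p, q),
    then particle–wall ascending (p, wall id).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    radii = np.asarray(radii, dtype=float)
    n = pos.shape[0]
    events: list[CollisionEvent] = []

    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]  # (n, n, 3)
        dist = np.linalg.norm(diff, axis=-1)
        contact = radii[:, None] + radii[None, :]
        iu = np.triu_indices(n, k=1)
        hit = dist[iu] < contact[iu]
        for p, q in zip(iu[0][hit], iu[1][hit]):
            events.append(
                CollisionEvent("pp", int(p), int(q), collision_normal(pos[p], pos[q]))
            )

    if walls is not None:
        for p in range(n):
            for wall_id, wall in enumerate(walls):
                dist, n_hat = wall.signed_distance(pos[p])
                if dist < radii[p]:
                    events.append(CollisionEvent("pw", p, wall_id, np.asarray(n_hat, float)))
    return events


def apply_adjustments(
    pre_positions,
    predicted_positions,
    predicted_velocities,
    masses,
    events,
    dt,
):
    """Apply collision corrections for one time step (single pass).

    For every particle named in ``events`` the predicted velocity is
    replaced by its collision-resolved value and the position is
    re-advanced from the *pre-step* position, ``r_adj = r_i + v_adj*dt``.
    Unaffected particles keep their predicted state.  Particle–particle
    events are processed first in ascending order; a wall reflection is
    then applied to the (possibly already adjusted) velocity.
    """
    pre = np.atleast_2d(np.asarray(pre_positions, dtype=float))
    pos = np.atleast_2d(np.asarray(predicted_positions, dtype=float)).copy()
    vel = np.atleast_2d(np.asarray(predicted_velocities, dtype=float)).copy()
    masses = np.asarray(masses, dtype=float)
    if not events:
        return pos, vel

    touched: set[int] = set()
    for ev in sorted(events, key=lambda e: (e.kind != "pp", e.p, e.q)):
        if ev.kind == "pp":
            vp, vq = resolve_particle_collision(
                vel[ev.p], vel[ev.q], masses[ev.p], masses[ev.q], ev.n_hat
            )
            vel[ev.p], vel[ev.q] = vp, vq
            touched.update((ev.p, ev.q))
        else:
            vel[ev.p] = resolve_wall_collision(vel[ev.p], ev.n_hat)
            touched.add(ev.p)

    idx = sorted(touched)
    pos[idx] = pre[idx] + vel[idx] * dt
    return pos, vel
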