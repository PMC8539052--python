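import numpy as np
import pytest

from locsim.collisions import (
    apply_adjustments,
    collision_normal,
    detect_collisions,
    resolve_particle_collision,
    resolve_wall_collision,
)
from locsim.errors import DomainError
from locsim.geometry import PlaneWall, WallSet


class TestCollisionNormal:
    def test_axis_aligned(self):
        np.testing.assert_allclose(collision_normal([2, 0, 0], [0, 0, 0]), [1, 0, 0])

    def test_diagonal(self):
        np.testing.assert_allclose(
            collision_normal([1, 1, 0], [0, 0, 0]), [1 / np.sqrt(2), 1 / np.sqrt(2), 0]
        )

    def test_antisymmetry(self, rng):
        rp, rq = rng.normal(size=3), rng.normal(size=3)
        np.testing.assert_allclose(collision_normal(rp, rq), -collision_normal(rq, rp))

    def test_coincident_centres_fall_back_to_vertical(self):
        np.testing.assert_array_equal(collision_normal([1, 1, 1], [1, 1, 1]), [0, 0, 1])


class TestParticleCollision:
    def test_equal_mass_head_on_swaps_velocities(self):
        vp, vq = resolve_particle_collision([1, 0, 0], [-1, 0, 0], 1.0, 1.0, [1, 0, 0])
        np.testing.assert_allclose(vp, [-1, 0, 0])
        np.testing.assert_allclose(vq, [1, 0, 0])

    def test_unequal_mass_one_dimensional_formula(self):
        # mp=1 hits resting mq=3: vp' = (mp-mq)/(mp+mq)*vp = -1, vq' = 2mp/(mp+mq)*vp = 1
        vp, vq = resolve_particle_collision([2, 0, 0], [0, 0, 0], 1.0, 3.0, [1, 0, 0])
        np.testing.assert_allclose(vp, [-1, 0, 0])
        np.testing.assert_allclose(vq, [1, 0, 0])
        # momentum 1*2=2 and kinetic energy 0.5*1*4=2 preserved
        assert 1 * vp[0] + 3 * vq[0] == pytest.approx(2.0)
        assert 0.5 * 1 * vp @ vp + 0.5 * 3 * vq @ vq == pytest.approx(2.0)

    def test_grazing_contact_unchanged(self):
        vp, vq = resolve_particle_collision([0, 1, 0], [0, 1, 0], 1.0, 2.0, [1, 0, 0])
        np.testing.assert_allclose(vp, [0, 1, 0])
        np.testing.assert_allclose(vq, [0, 1, 0])

    def test_conservation_over_random_configurations(self, rng):
        # momentum and kinetic energy to <= 1e-12 relative over 1e4 resolutions
        for _ in range(10_000):
            vp, vq = rng.normal(size=(2, 3))
            mp, mq = rng.uniform(0.1, 10.0, size=2)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            vp2, vq2 = resolve_particle_collision(vp, vq, mp, mq, n)
            p_before = mp * vp + mq * vq
            p_after = mp * vp2 + mq * vq2
            ke_before = 0.5 * (mp * vp @ vp + mq * vq @ vq)
            ke_after = 0.5 * (mp * vp2 @ vp2 + mq * vq2 @ vq2)
            np.testing.assert_allclose(p_after, p_before, rtol=1e-12, atol=1e-12)
            assert ke_after == pytest.approx(ke_before, rel=1e-12)

    def test_frame_consistency(self, rng):
        # boosting both incoming velocities boosts both outgoing ones equally
        vp, vq, boost = rng.normal(size=(3, 3))
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        a = resolve_particle_collision(vp, vq, 1.3, 2.7, n)
        b = resolve_particle_collision(vp + boost, vq + boost, 1.3, 2.7, n)
        np.testing.assert_allclose(b[0], a[0] + boost, rtol=1e-12)
        np.testing.assert_allclose(b[1], a[1] + boost, rtol=1e-12)

    def test_infinite_partner_mass_limit_is_wall_reflection(self, rng):
        v = rng.normal(size=3)
        n = np.array([0.0, 0.0, 1.0])
        vp, _ = resolve_particle_collision(v, np.zeros(3), 1.0, 1e12, n)
        np.testing.assert_allclose(vp, resolve_wall_collision(v, n), rtol=1e-9)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(DomainError):
            resolve_particle_collision([1, 0, 0], [0, 0, 0], 1.0, 1.0, [2, 0, 0])


class TestWallCollision:
    def test_mirror_reflection_off_floor(self):
        np.testing.assert_allclose(resolve_wall_collision([1, 2, -3], [0, 0, 1]), [1, 2, 3])

    def test_tangential_motion_unchanged(self):
        np.testing.assert_allclose(resolve_wall_collision([5, -7, 0], [0, 0, 1]), [5, -7, 0])

    def test_reflection_is_an_isometry(self, rng):
        for _ in range(10_000):
            v = rng.normal(size=3)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            v2 = resolve_wall_collision(v, n)
            assert np.linalg.norm(v2) == pytest.approx(np.linalg.norm(v), rel=1e-12)
            # tangential component preserved exactly
            np.testing.assert_allclose(
                v2 - (v2 @ n) * n, v - (v @ n) * n, rtol=1e-9, atol=1e-12
            )


class TestDetection:
    floor = WallSet([PlaneWall((0, 0, 0), (0, 0, 1), name="floor")])

    def test_separated_pair_not_flagged(self):
        events = detect_collisions([[0, 0, 10], [3, 0, 10]], [1.0, 1.0])
        assert events == []

    def test_overlapping_pair_flagged(self):
        events = detect_collisions([[0, 0, 10], [1.9, 0, 10]], [1.0, 1.0])
        assert len(events) == 1
        assert (events[0].kind, events[0].p, events[0].q) == ("pp", 0, 1)

    def test_wall_penetration_flagged(self):
        events = detect_collisions([[0, 0, 1.5]], [2.0], self.floor)
        assert len(events) == 1
        assert events[0].kind == "pw"
        np.testing.assert_array_equal(events[0].n_hat, [0, 0, 1])

    def test_particle_above_contact_not_flagged(self):
        assert detect_collisions([[0, 0, 2.5]], [2.0], self.floor) == []


class TestAdjustments:
    def test_empty_event_list_is_identity(self):
        pre = np.array([[0.0, 0.0, 5.0]])
        pred = np.array([[1.0, 0.0, 5.0]])
        vel = np.array([[1.0, 0.0, 0.0]])
        pos2, vel2 = apply_adjustments(pre, pred, vel, [1.0], [], 1.0)
        np.testing.assert_array_equal(pos2, pred)
        np.testing.assert_array_equal(vel2, vel)

    def test_floor_bounce_reverses_vertical_motion(self):
        # falling particle through the floor: velocity flips up, position
        # re-advances from the pre-step height
        floor = WallSet([PlaneWall((0, 0, 0), (0, 0, 1), name="floor")])
        pre = np.array([[0.0, 0.0, 3e-6]])
        vel = np.array([[0.0, 0.0, -2e-6]])
        dt = 1.0
        pred = pre + vel * dt  # z = 1 um < ro = 2 um
        events = detect_collisions(pred, [2e-6], floor)
        pos2, vel2 = apply_adjustments(pre, pred, vel, [1e-14], events, dt)
        assert vel2[0, 2] == pytest.approx(2e-6)
        assert pos2[0, 2] == pytest.approx(5e-6)
        assert pos2[0, 2] >= pre[0, 2]

    def test_symmetric_approach_separates(self):
        pre = np.array([[-1.5e-6, 0, 10e-6], [1.5e-6, 0, 10e-6]])
        vel = np.array([[1e-6, 0, 0], [-1e-6, 0, 0]])
        dt = 1.0
        pred = pre + vel * dt
        events = detect_collisions(pred, [1e-6, 1e-6])
        assert len(events) == 1
        pos2, vel2 = apply_adjustments(pre, pred, vel, [1e-14, 1e-14], events, dt)
        gap_before = np.linalg.norm(pred[0] - pred[1])
        gap_after = np.linalg.norm(pos2[0] - pos2[1])
        assert gap_after > gap_before
        # equal masses: velocities swap
        np.testing.assert_allclose(vel2[0], [-1e-6, 0, 0])
        np.testing.assert_allclose(vel2[1], [1e-6, 0, 0])
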