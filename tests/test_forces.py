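import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locsim import Medium
from locsim.constants import KB
from locsim.core import sphere_volume
from locsim.dielectrics import (
    ShellLayer,
    ShellSpec,
    cm_factor,
    complex_permittivity,
    effective_properties,
    load_yeast_cells,
    medium_complex_permittivity,
    multishell_effective_permittivity,
)
from locsim.errors import ConfigurationError, DomainError
from locsim.forces import (
    DEPForce,
    GaussianTrap,
    GravityBuoyancy,
    ParticleArrays,
    TimeGated,
    resolve_re_cm,
    sum_forces,
)

T = 300.0
UM = 1e-6


def _particles(ro, re_cm=None):
    ro = np.atleast_1d(np.asarray(ro, dtype=float))
    vol = np.array([sphere_volume(r) for r in ro])
    return ParticleArrays(
        radius=ro,
        mass=vol * 1055.0,
        volume=vol,
        re_cm=None if re_cm is None else np.atleast_1d(np.asarray(re_cm, dtype=float)),
    )


def _trap(ad_kbt_um3=120.0, w_um=10.0):
    return GaussianTrap(ad=ad_kbt_um3 * KB * T / UM**3, w=w_um * UM)


class TestGaussianTrap:
    def test_well_depth_at_centre(self):
        # 2 um bead, Ad = 120 kBT/um^3: |u(0)| = (4/3) pi ro^3 Ad
        u0 = _trap().potential(np.zeros(3), _particles(2e-6))
        assert u0[0] == pytest.approx(-1.666e-17, rel=1e-3)
        assert abs(u0[0]) / (KB * T) == pytest.approx(4023, rel=1e-3)

    def test_potential_vanishes_far_away(self):
        u = _trap().potential(np.array([1e-3, 0, 0]), _particles(2e-6))
        assert u[0] == pytest.approx(0.0, abs=1e-30)

    def test_volume_scaling(self):
        u1 = _trap().potential(np.zeros(3), _particles(1e-6))
        u2 = _trap().potential(np.zeros(3), _particles(2e-6))
        assert u2[0] == pytest.approx(8 * u1[0])

    def test_zero_force_at_centre_by_symmetry(self):
        f = _trap().force(np.zeros((1, 3)), 0.0, _particles(2e-6))
        np.testing.assert_allclose(f, 0.0)

    def test_maximum_restoring_force(self):
        # |F_r| peaks at r = w/sqrt(2); ~1.43 pN for the reference bead
        trap = _trap()
        r = np.array([[10e-6 / np.sqrt(2), 0, 0]])
        f = trap.force(r, 0.0, _particles(2e-6))
        assert np.linalg.norm(f) == pytest.approx(1.43e-12, rel=5e-3)
        # nearby radii give weaker force
        for rr in (6e-6, 8e-6):
            fr = trap.force(np.array([[rr, 0, 0]]), 0.0, _particles(2e-6))
            assert np.linalg.norm(fr) < np.linalg.norm(f)

    def test_force_points_toward_centre(self, rng):
        trap = _trap()
        pts = rng.uniform(-20e-6, 20e-6, size=(50, 3))
        f = trap.force(pts, 0.0, _particles([2e-6] * 50))
        assert np.all(np.sum(f * pts, axis=1) < 0)

    def test_force_is_negative_gradient_of_potential(self, rng):
        # central-difference oracle at random points
        trap = _trap()
        particles = _particles(2e-6)
        h = 1e-9
        for _ in range(20):
            r = rng.uniform(-15e-6, 15e-6, size=3)
            f = trap.force(r[None, :], 0.0, particles)[0]
            grad = np.empty(3)
            for k in range(3):
                e = np.zeros(3)
                e[k] = h
                up = trap.potential(r + e, particles)[0]
                dn = trap.potential(r - e, particles)[0]
                grad[k] = (up - dn) / (2 * h)
            np.testing.assert_allclose(f, -grad, rtol=1e-6, atol=1e-18)


class TestTimeGate:
    def test_gate_window(self):
        gated = TimeGated(_trap(), 1.0, 8.0)
        r = np.array([[5e-6, 0, 0]])
        p = _particles(2e-6)
        np.testing.assert_array_equal(gated.force(r, 0.5, p), 0.0)
        np.testing.assert_array_equal(gated.force(r, 9.0, p), 0.0)
        np.testing.assert_allclose(gated.force(r, 4.5, p), _trap().force(r, 4.5, p))

    def test_invalid_gate_rejected(self):
        with pytest.raises(DomainError):
            TimeGated(_trap(), 8.0, 1.0)


class TestComplexPermittivity:
    def test_lossless_material_is_real(self):
        assert complex_permittivity(80.0, 0.0, 5e6) == 80.0

    def test_loss_term_value(self):
        # sigma/(2 pi f eps0) at 5 MHz
        eps = complex_permittivity(80.0, 0.013, 5e6)
        assert eps.real == 80.0
        assert eps.imag == pytest.approx(-46.73, rel=1e-3)

    def test_imaginary_part_scales_inversely_with_frequency(self):
        a = complex_permittivity(80.0, 0.1, 1e6)
        b = complex_permittivity(80.0, 0.1, 2e6)
        assert a.imag == pytest.approx(2 * b.imag)

    def test_non_positive_frequency_rejected(self):
        with pytest.raises(DomainError):
            complex_permittivity(80.0, 0.1, 0.0)


class TestMultiShell:
    def test_single_layer_passthrough(self):
        spec = ShellSpec((ShellLayer(1e-6, 50.0, 0.1),))
        assert multishell_effective_permittivity(spec, 1e6) == complex_permittivity(50.0, 0.1, 1e6)

    def test_identical_shell_collapses_to_core(self):
        spec = ShellSpec((ShellLayer(1e-6, 50.0, 0.1), ShellLayer(2e-6, 50.0, 0.1)))
        eq = multishell_effective_permittivity(spec, 1e6)
        assert eq == pytest.approx(complex_permittivity(50.0, 0.1, 1e6), rel=1e-12)

    def test_vanishing_shell_thickness_recovers_core(self):
        core = ShellLayer(1e-6, 30.0, 0.2)
        thin = ShellSpec((core, ShellLayer(1e-6 + 1e-14, 5.0, 1e-6)))
        eq = multishell_effective_permittivity(thin, 5e6)
        assert eq == pytest.approx(complex_permittivity(30.0, 0.2, 5e6), rel=1e-4)

    def test_yeast_effective_properties_at_5mhz(self):
        # the bundled cell data must reproduce the reference effective values
        yeast = load_yeast_cells()
        eps_v, sig_v = effective_properties(yeast["viable"], 5e6)
        eps_n, sig_n = effective_properties(yeast["nonviable"], 5e6)
        assert eps_v == pytest.approx(199.94, abs=0.005)
        assert sig_v == pytest.approx(0.36, abs=0.005)
        assert eps_n == pytest.approx(18.82, abs=0.005)
        assert sig_n == pytest.approx(0.013, abs=0.0005)

    def test_layer_ordering_validated(self):
        with pytest.raises(DomainError):
            ShellSpec((ShellLayer(2e-6, 50.0, 0.1), ShellLayer(1e-6, 5.0, 0.1)))


class TestCMFactor:
    def test_index_matched_is_zero(self):
        assert cm_factor(80 + 0j, 80 + 0j) == 0.0

    def test_high_contrast_limit(self):
        assert cm_factor(1e9 + 0j, 80 + 0j).real == pytest.approx(1.0, abs=1e-6)

    @settings(deadline=None, max_examples=200)
    @given(
        eps_p=st.floats(1.0, 1e4),
        sig_p=st.floats(0.0, 10.0),
        eps_m=st.floats(1.0, 100.0),
        sig_m=st.floats(0.0, 10.0),
    )
    def test_real_part_bounded_for_passive_materials(self, eps_p, sig_p, eps_m, sig_m):
        cm = cm_factor(
            complex_permittivity(eps_p, sig_p, 5e6), complex_permittivity(eps_m, sig_m, 5e6)
        )
        assert -0.5 - 1e-9 <= cm.real <= 1.0 + 1e-9

    def test_yeast_cm_values_at_5mhz(self):
        yeast = load_yeast_cells()
        f = yeast["frequency_Hz"]
        medium = Medium(eta=8.9e-4, T=300.0, eps_m=yeast["medium"]["eps_m"],
                        sigma_m=yeast["medium"]["sigma_S_per_m"])
        em = medium_complex_permittivity(medium, f)
        cm_v = cm_factor(multishell_effective_permittivity(yeast["viable"], f), em)
        cm_n = cm_factor(multishell_effective_permittivity(yeast["nonviable"], f), em)
        assert cm_v.real == pytest.approx(0.945, abs=0.005)
        assert cm_n.real == pytest.approx(-0.25, abs=0.005)
        assert abs(cm_n.real) / abs(cm_v.real) == pytest.approx(0.26, abs=0.01)


class TestDEPForce:
    uniform_grad = type(
        "G", (), {"gradient": staticmethod(lambda r: np.broadcast_to([1e15, 0, 0], r.shape).copy())}
    )()

    def test_closed_form_magnitude(self, water):
        # ro=3 um, eps_m=80, ReCM=0.945, grad|E|^2 = 1e15 V^2/m^3
        dep = DEPForce(self.uniform_grad, water, 5e6)
        f = dep.force(np.zeros((1, 3)), 0.0, _particles(3e-6, re_cm=0.945))
        assert f[0, 0] == pytest.approx(1.136e-10, rel=1e-3)

    def test_zero_cm_gives_zero_force(self, water):
        dep = DEPForce(self.uniform_grad, water, 5e6)
        f = dep.force(np.zeros((1, 3)), 0.0, _particles(3e-6, re_cm=0.0))
        np.testing.assert_array_equal(f, 0.0)

    def test_sign_flip_reverses_force(self, water):
        dep = DEPForce(self.uniform_grad, water, 5e6)
        fp = dep.force(np.zeros((1, 3)), 0.0, _particles(3e-6, re_cm=0.5))
        fn = dep.force(np.zeros((1, 3)), 0.0, _particles(3e-6, re_cm=-0.5))
        np.testing.assert_allclose(fn, -fp)

    def test_nonviable_force_is_viable_scaled_by_cm_ratio(self, water):
        yeast = load_yeast_cells()
        f = yeast["frequency_Hz"]
        medium = Medium(eta=8.9e-4, T=300.0, eps_m=yeast["medium"]["eps_m"],
                        sigma_m=yeast["medium"]["sigma_S_per_m"])
        cm_v = resolve_re_cm(yeast["viable"], medium, f)
        cm_n = resolve_re_cm(yeast["nonviable"], medium, f)
        dep = DEPForce(self.uniform_grad, medium, f)
        fv = dep.force(np.zeros((1, 3)), 0.0, _particles(3e-6, re_cm=cm_v))
        fn = dep.force(np.zeros((1, 3)), 0.0, _particles(3e-6, re_cm=cm_n))
        ratio = np.linalg.norm(fn) / np.linalg.norm(fv)
        assert ratio == pytest.approx(abs(cm_n) / abs(cm_v), rel=1e-12)
        assert ratio == pytest.approx(0.26, abs=0.01)
        assert np.sign(fn[0, 0]) == -np.sign(fv[0, 0])

    def test_missing_dielectric_model_rejected(self, water):
        dep = DEPForce(self.uniform_grad, water, 5e6)
        with pytest.raises(ConfigurationError):
            dep.force(np.zeros((1, 3)), 0.0, _particles(3e-6))


class TestGravityBuoyancy:
    def test_neutral_buoyancy(self):
        medium = Medium(eta=8.9e-4, T=300.0, rho_f=1055.0)
        f = GravityBuoyancy(medium).force(np.zeros((1, 3)), 0.0, _particles(2e-6))
        np.testing.assert_allclose(f, 0.0, atol=1e-25)

    def test_polystyrene_in_water(self, water):
        f = GravityBuoyancy(water).force(np.zeros((1, 3)), 0.0, _particles(2e-6))
        assert f[0, 2] == pytest.approx(-1.81e-14, rel=2e-3)

    def test_light_particle_floats(self):
        medium = Medium(eta=8.9e-4, T=300.0, rho_f=2000.0)
        f = GravityBuoyancy(medium).force(np.zeros((1, 3)), 0.0, _particles(2e-6))
        assert f[0, 2] > 0

    def test_missing_density_rejected(self):
        with pytest.raises(ConfigurationError):
            GravityBuoyancy(Medium(eta=8.9e-4, T=300.0))


class TestSuperposition:
    def test_zero_field_changes_nothing(self, water):
        zero = type("Z", (), {"force": staticmethod(lambda r, t, p: np.zeros(r.shape))})()
        trap = _trap()
        p = _particles(2e-6)
        r = np.array([[5e-6, 1e-6, 3e-6]])
        np.testing.assert_array_equal(
            sum_forces([trap], r, 2.0, p), sum_forces([trap, zero], r, 2.0, p)
        )
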