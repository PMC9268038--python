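import math

import numpy as np
import pytest

from vibronic.core_io import AMU_TO_ME, BOHR_TO_ANGSTROM, HARTREE_TO_CM, \
    ElectronicStateBundle, ValidationError
from vibronic.fc_ti import FCOverlapEngine
from vibronic.harmonic_analysis import normal_modes, project_gradient
from vibronic.model_systems import make_random_bundle
from vibronic.vibronic_models import DuschinskyMap, build_map, mode_activity


def clone(bundle, **kwargs):
    base = dict(label=bundle.label, elements=bundle.elements,
                geometry=bundle.geometry, masses=bundle.masses,
                energy=bundle.energy, hessian=bundle.hessian,
                gradient=bundle.gradient)
    base.update(kwargs)
    return ElectronicStateBundle(**base)


def breathing_displaced(bundle, scale):
    """Displace uniformly about the center of mass: Eckart-frame-exact."""
    com = np.average(bundle.geometry, axis=0, weights=bundle.masses)
    return com + (1.0 + scale) * (bundle.geometry - com)


@pytest.fixture
def ground():
    return make_random_bundle(4, seed=42)


class TestBuildMapBasics:
    def test_identical_states_any_model(self, ground):
        final = clone(ground, energy=ground.energy + 0.08)
        for model in ("AH", "AS"):
            dmap = build_map(ground, final, model)
            assert np.abs(dmap.J - np.eye(dmap.nvib)).max() < 1e-9
            assert np.abs(dmap.K).max() < 1e-9
            assert dmap.Evert == pytest.approx(dmap.E00, rel=1e-12)
            assert dmap.E00 == pytest.approx(0.08 * HARTREE_TO_CM, rel=1e-10)

    def test_vg_zero_gradient(self, ground):
        final = clone(ground, energy=0.09, gradient=np.zeros(3 * ground.natoms),
                      hessian=None)
        dmap = build_map(ground, final, "VG")
        np.testing.assert_allclose(dmap.K, 0.0, atol=1e-14)
        assert dmap.Evert == pytest.approx(dmap.E00, rel=1e-12)

    def test_missing_ingredient_errors(self, ground):
        no_hessian = clone(ground, hessian=None, energy=0.05)
        with pytest.raises(ValidationError, match="AH"):
            build_map(ground, no_hessian, "AH")
        with pytest.raises(ValidationError, match="VG"):
            build_map(ground, clone(ground, energy=0.05, gradient=None), "VG")

    def test_vertical_models_need_initial_geometry(self, ground):
        displaced = clone(ground, geometry=ground.geometry + 0.1,
                          gradient=np.zeros(3 * ground.natoms))
        with pytest.raises(ValidationError, match="initial geometry"):
            build_map(ground, displaced, "VG")


class TestVG:
    def test_single_mode_k_value(self, diatomic_bundle):
        basis = normal_modes(diatomic_bundle)
        w_au = basis.frequencies_au[0]
        g_q = 1e-4
        sqrt_m = np.sqrt(np.repeat(diatomic_bundle.masses_me, 3))
        g_cart = sqrt_m * (basis.modes[:, 0] * g_q)
        final = clone(diatomic_bundle, energy=0.09, gradient=g_cart, hessian=None)
        dmap = build_map(diatomic_bundle, final, "VG")
        assert dmap.K[0] == pytest.approx(-g_q / w_au ** 2, rel=1e-10)
        assert dmap.K[0] == pytest.approx(-4.817, abs=2e-3)
        activity = mode_activity(dmap)
        assert activity.huang_rhys[0] == pytest.approx(0.05286, abs=2e-5)

    def test_as_equals_vg_for_harmonic_surface(self, ground):
        # same final curvature as initial, minimum displaced along the modes:
        # the gradient route and the geometry route must give identical K
        basis = normal_modes(ground)
        rng = np.random.default_rng(5)
        k_target = rng.normal(scale=3.0, size=basis.nvib)
        sqrt_m = np.sqrt(np.repeat(ground.masses_me, 3))
        dx_bohr = (basis.modes @ k_target) / sqrt_m
        geom_f = ground.geometry + dx_bohr.reshape(-1, 3) * BOHR_TO_ANGSTROM
        e00_h = 0.083
        w2 = basis.frequencies_au ** 2
        lam_h = 0.5 * float(np.sum(w2 * k_target ** 2))

        final_min = clone(ground, geometry=geom_f, energy=e00_h, hessian=None)
        as_map = build_map(ground, final_min, "AS")

        g_cart = sqrt_m * (basis.modes @ (-w2 * k_target))
        final_vert = clone(ground, energy=e00_h + lam_h, gradient=g_cart,
                           hessian=None)
        vg_map = build_map(ground, final_vert, "VG")

        np.testing.assert_allclose(as_map.K, vg_map.K, atol=1e-10)
        np.testing.assert_allclose(as_map.K, k_target, atol=1e-10)
        assert as_map.Evert == pytest.approx(vg_map.Evert, rel=1e-8)
        assert as_map.E00 == pytest.approx(vg_map.E00, rel=1e-8)


class TestAH:
    def test_reduces_to_as_without_mixing(self, ground):
        final = clone(ground, geometry=breathing_displaced(ground, 0.02),
                      energy=0.08)
        ah = build_map(ground, final, "AH")
        as_ = build_map(ground, clone(final, hessian=None), "AS")
        assert np.abs(ah.J - np.eye(ah.nvib)).max() < 1e-10
        np.testing.assert_allclose(ah.K, as_.K, atol=1e-10)
        np.testing.assert_allclose(ah.freqs_final, as_.freqs_final, atol=1e-6)

    def test_rotated_fixture_recovers_rotation(self, rotated_bundles):
        spec, (dmap, initial, final) = rotated_bundles
        r = spec.rotation_matrix()
        assert np.abs(dmap.J[:2, :2] - r).max() < 1e-10
        assert np.abs(dmap.J @ dmap.J.T - np.eye(dmap.nvib)).max() < 1e-10

    def test_reorganization_identity_j_identity(self, ground):
        final = clone(ground, geometry=breathing_displaced(ground, 0.015),
                      energy=0.085)
        dmap = build_map(ground, final, "AH")
        activity = mode_activity(dmap)
        lam_from_s = float(np.sum(activity.huang_rhys * dmap.freqs_initial))
        assert dmap.Evert - dmap.E00 == pytest.approx(lam_from_s, rel=1e-6)
        assert activity.reorganization_cm1 == pytest.approx(lam_from_s, rel=1e-9)


class TestVH:
    @pytest.fixture
    def vh_world(self, ground):
        """Analytic final surface with rotation, frequency change and shift,
        expressed as vertical (Hessian + gradient at the initial minimum)."""
        basis = normal_modes(ground)
        n = basis.nvib
        th = math.radians(20.0)
        j = np.eye(n)
        j[:2, :2] = [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
        wp_au = basis.frequencies_au * np.linspace(1.05, 0.92, n)
        a = j.T @ np.diag(wp_au ** 2) @ j
        rng = np.random.default_rng(9)
        k_target = rng.normal(scale=2.0, size=n)
        sqrt_m = np.sqrt(np.repeat(ground.masses_me, 3))
        h_mw = basis.modes @ a @ basis.modes.T
        hessian = h_mw * np.outer(sqrt_m, sqrt_m)
        g_cart = sqrt_m * (basis.modes @ (-a @ k_target))
        evert_h = 0.09
        final = clone(ground, energy=evert_h, hessian=hessian, gradient=g_cart)
        return basis, j, wp_au, k_target, evert_h, final

    def test_vh_recovers_surface(self, ground, vh_world):
        basis, j, wp_au, k_target, evert_h, final = vh_world
        dmap = build_map(ground, final, "VH")
        np.testing.assert_allclose(np.sort(dmap.freqs_final),
                                   np.sort(wp_au * HARTREE_TO_CM), rtol=1e-8)
        np.testing.assert_allclose(dmap.K, k_target, atol=1e-8)
        assert dmap.Evert == pytest.approx(evert_h * HARTREE_TO_CM, rel=1e-10)
        lam = 0.5 * float(k_target @ (j.T @ np.diag(wp_au ** 2) @ j) @ k_target)
        assert dmap.E00 == pytest.approx((evert_h - lam) * HARTREE_TO_CM, rel=1e-8)

    def test_vh_imaginary_hard_error(self, ground):
        basis = normal_modes(ground)
        a = np.diag(basis.frequencies_au ** 2)
        a[0, 0] *= -1.0
        sqrt_m = np.sqrt(np.repeat(ground.masses_me, 3))
        hessian = (basis.modes @ a @ basis.modes.T) * np.outer(sqrt_m, sqrt_m)
        final = clone(ground, energy=0.09, hessian=hessian,
                      gradient=np.zeros(3 * ground.natoms))
        with pytest.raises(ValidationError, match="imaginary"):
            build_map(ground, final, "VH")
        dropped = build_map(ground, final, "VH", drop_imaginary=True)
        assert dropped.nvib == basis.nvib - 1
        assert np.all(dropped.freqs_final > 0)


class TestDuschinskyMapType:
    def test_non_orthogonal_j_rejected(self):
        with pytest.raises(ValidationError, match="orthogonal"):
            DuschinskyMap("AH", np.array([[1.0, 0.4], [0.0, 1.0]]),
                          [0.0, 0.0], [1000.0, 1200.0], [1000.0, 1200.0],
                          18000.0, 18000.0)

    def test_as_requires_identity(self):
        th = math.radians(10)
        j = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        with pytest.raises(ValidationError, match="identity"):
            DuschinskyMap("AS", j, [0.0, 0.0], [1000.0, 1200.0],
                          [1000.0, 1200.0], 18000.0, 18000.0)

    def test_e00_zpe(self):
        dmap = DuschinskyMap("AS", np.eye(1), [0.0], [1000.0], [1200.0],
                             18000.0, 18000.0)
        assert dmap.E00_zpe == pytest.approx(18100.0)

    def test_save_load_roundtrip(self, tmp_path, duschinsky_2mode):
        path = tmp_path / "map.json"
        duschinsky_2mode.save(path)
        back = DuschinskyMap.load(path)
        np.testing.assert_allclose(back.J, duschinsky_2mode.J, atol=1e-12)
        np.testing.assert_allclose(back.K, duschinsky_2mode.K, atol=1e-12)
        assert back.Evert == pytest.approx(duschinsky_2mode.Evert, rel=1e-12)


class TestModeActivity:
    def test_zero_displacement(self, ground):
        dmap = build_map(ground, clone(ground, energy=0.05), "AS")
        activity = mode_activity(dmap)
        np.testing.assert_allclose(activity.huang_rhys, 0.0, atol=1e-18)
        assert activity.reorganization_cm1 == pytest.approx(0.0, abs=1e-9)

    def test_lambda_equals_s_omega(self, displaced_map):
        activity = mode_activity(displaced_map)
        assert activity.huang_rhys[0] == pytest.approx(0.6, rel=1e-10)
        assert activity.reorganization_cm1 == pytest.approx(690.0, rel=1e-10)

    def test_phase_flip_leaves_intensities(self, duschinsky_2mode):
        m = duschinsky_2mode
        flipped = DuschinskyMap(
            m.model, m.J * np.array([-1.0, 1.0])[None, :],
            m.K * np.array([-1.0, 1.0]), m.freqs_initial, m.freqs_final,
            m.E00, m.Evert, m.transition_dipole)
        a = FCOverlapEngine(m)
        b = FCOverlapEngine(flipped)
        for v in [(0, 0), (1, 0), (2, 1)]:
            for vp in [(0, 0), (1, 1), (0, 3)]:
                assert a.fc_factor(v, vp) == pytest.approx(
                    b.fc_factor(v, vp), abs=1e-12)
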