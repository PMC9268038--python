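import math
import warnings
from itertools import product

import numpy as np
import pytest

from conftest import rotated_test_map
from oracles import freq_change_00, poisson_fc, quadrature_overlap
from vibronic.core_io import KB_CM_PER_K, ValidationError
from vibronic.fc_ti import (
    FCOverlapEngine, TruncationLimits, assignment_report,
    boltzmann_populations, fc_overlap, fundamental_fraction,
    sticks_thermal, sticks_zero_T,
)
from vibronic.model_systems import (
    ModelChromophoreSpec, make_cy3_like, make_displaced_oscillators,
)
from vibronic.vibronic_models import DuschinskyMap


def displaced(s, w=1150.0, e00=18200.0):
    spec = ModelChromophoreSpec(freqs_initial=np.atleast_1d(w),
                                huang_rhys=np.atleast_1d(s), E00=e00)
    return make_displaced_oscillators(spec)


class TestOverlaps:
    def test_identity_map_is_kronecker(self):
        dmap = DuschinskyMap("AS", np.eye(2), [0.0, 0.0],
                             [900.0, 1300.0], [900.0, 1300.0], 18000.0, 18000.0)
        eng = FCOverlapEngine(dmap)
        for v in product(range(3), repeat=2):
            for vp in product(range(3), repeat=2):
                expected = 1.0 if v == vp else 0.0
                assert eng.overlap(v, vp) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("s", [0.25, 0.5, 1.0, 2.0])
    def test_poisson_closed_form(self, s):
        eng = FCOverlapEngine(displaced(s))
        for n in range(11):
            assert eng.fc_factor([0], [n]) == pytest.approx(
                poisson_fc(s, n), abs=1e-8)

    def test_poisson_named_values(self):
        eng = FCOverlapEngine(displaced(1.0))
        assert eng.fc_factor([0], [0]) == pytest.approx(0.367879, abs=1e-6)
        assert eng.fc_factor([0], [1]) == pytest.approx(0.367879, abs=1e-6)
        assert eng.fc_factor([0], [2]) == pytest.approx(0.183940, abs=1e-6)

    def test_frequency_change_00(self):
        dmap = DuschinskyMap("AH", np.eye(1), [0.0], [1000.0], [2000.0],
                             18000.0, 18000.0)
        fc = FCOverlapEngine(dmap).fc_factor([0], [0])
        assert fc == pytest.approx(2.0 * math.sqrt(2.0) / 3.0, abs=1e-10)
        assert fc == pytest.approx(freq_change_00(1000.0, 2000.0), abs=1e-10)

    @pytest.mark.parametrize("nmodes,angle", [(2, 30.0), (2, 45.0), (3, 25.0)])
    def test_recursion_matches_quadrature(self, nmodes, angle):
        dmap = rotated_test_map(nmodes, angle)
        eng = FCOverlapEngine(dmap)
        rng = np.random.default_rng(0)
        picks = [tuple(rng.integers(0, 5, size=nmodes)) for _ in range(6)]
        for v in [(0,) * nmodes] + picks[:3]:
            for vp in [(0,) * nmodes] + picks[3:]:
                assert eng.overlap(v, vp) == pytest.approx(
                    quadrature_overlap(dmap, v, vp), abs=1e-8)

    def test_fc_overlap_function(self, displaced_map):
        assert fc_overlap(displaced_map, [0], [0]) ** 2 == pytest.approx(
            math.exp(-0.6), rel=1e-10)

    def test_negative_quanta_rejected(self, displaced_map):
        with pytest.raises(ValidationError):
            FCOverlapEngine(displaced_map).overlap([-1], [0])

    def test_imaginary_frequency_rejected(self):
        dmap = DuschinskyMap("AH", np.eye(1), [0.0], [1000.0], [-300.0],
                             18000.0, 18000.0)
        with pytest.raises(ValidationError, match="positive"):
            FCOverlapEngine(dmap)

    def test_sum_rule(self):
        # FC factors from |0> sum to <= 1, and are nearly complete for
        # small maps with S <= 1
        for dmap in [displaced(0.8), rotated_test_map(2, 20.0, (4.0, -3.0)),
                     rotated_test_map(3, 15.0, (4.0, -3.0, 2.0))]:
            eng = FCOverlapEngine(dmap)
            n = dmap.nvib
            total = sum(eng.fc_factor((0,) * n, vp)
                        for vp in product(range(11), repeat=n))
            assert total <= 1.0 + 1e-10
            assert total >= 0.999


class TestSticksZeroT:
    def test_origin_only(self):
        dmap = displaced(0.0)
        sticks = sticks_zero_T(dmap)
        assert len(sticks) == 1
        assert sticks.intensities[0] > 0
        assert sticks.energies[0] == pytest.approx(dmap.E00, abs=1e-9)

    def test_two_mode_enumeration(self):
        spec = ModelChromophoreSpec(freqs_initial=[1000.0, 1300.0],
                                    huang_rhys=[1.0, 0.5], E00=18000.0)
        dmap = make_displaced_oscillators(spec)
        limits = TruncationLimits(max_quanta=2, max_simultaneous=2,
                                  stick_floor=0.0, completeness_floor=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # completeness floor disabled
            sticks = sticks_zero_T(dmap, limits, frequency_prefactor=False)
        assert len(sticks) == 9
        combo = (sticks.final_quanta == [1, 1]).all(axis=1)
        assert sticks.intensities[combo][0] == pytest.approx(
            math.exp(-1.5) * 1.0 * 0.5, abs=1e-6)
        assert sticks.intensities[combo][0] == pytest.approx(0.111565, abs=1e-6)

    def test_poisson_tail_capture(self):
        sticks = sticks_zero_T(displaced(0.6), TruncationLimits(max_quanta=10),
                               frequency_prefactor=False)
        assert sticks.meta["fc_captured"] >= 0.9999

    def test_completeness_warning(self):
        limits = TruncationLimits(max_quanta=1, completeness_floor=0.99)
        with pytest.warns(UserWarning, match="captured"):
            sticks_zero_T(displaced(2.0), limits)

    def test_stick_energies_consistent(self, duschinsky_2mode):
        sticks = sticks_zero_T(duschinsky_2mode,
                               TruncationLimits(max_quanta=5))
        expected = (duschinsky_2mode.E00
                    + sticks.final_quanta @ duschinsky_2mode.freqs_final
                    - sticks.init_quanta @ duschinsky_2mode.freqs_initial)
        np.testing.assert_allclose(sticks.energies, expected, atol=1e-6)


class TestBoltzmann:
    def test_zero_temperature(self):
        pops, captured = boltzmann_populations([1000.0, 34.9], 0.0)
        assert pops == [((0, 0), 1.0)]
        assert captured == 1.0

    def test_soft_mode_population(self):
        pops, _ = boltzmann_populations([34.9], 298.0, floor=1e-8)
        p0 = dict(pops)[(0,)]
        x = 34.9 / (KB_CM_PER_K * 298.0)
        assert x == pytest.approx(0.16850, abs=2e-4)
        assert p0 == pytest.approx(1.0 - math.exp(-x), rel=1e-12)
        assert p0 == pytest.approx(0.15507, abs=1e-5)

    def test_stiff_mode_population(self):
        pops, _ = boltzmann_populations([1525.0], 298.0)
        assert dict(pops)[(0,)] > 0.999

    def test_negative_temperature(self):
        with pytest.raises(ValidationError):
            boltzmann_populations([1000.0], -1.0)


class TestSticksThermal:
    def test_zero_T_limit(self, duschinsky_2mode):
        limits = TruncationLimits(max_quanta=6)
        cold = sticks_zero_T(duschinsky_2mode, limits)
        thermal = sticks_thermal(duschinsky_2mode, 0.0, limits)
        np.testing.assert_allclose(np.sort(cold.energies),
                                   np.sort(thermal.energies), atol=1e-12)
        np.testing.assert_allclose(np.sort(cold.intensities),
                                   np.sort(thermal.intensities), atol=1e-12)

    def test_hot_band_dominance_soft_mode(self):
        dmap = displaced(0.7, w=34.9)
        sticks = sticks_thermal(dmap, 298.0, TruncationLimits(max_quanta=30),
                                population_floor=1e-7,
                                frequency_prefactor=False)
        hot = sticks.init_quanta.sum(axis=1) > 0
        assert sticks.intensities[hot].sum() / sticks.total_intensity > 0.5

    def test_classical_limit_first_moment(self):
        # kB T >> w: the intensity-weighted mean stick energy approaches Evert
        dmap = displaced(0.5, w=100.0)
        sticks = sticks_thermal(dmap, 2000.0,
                                TruncationLimits(max_quanta=320,
                                                 completeness_floor=0.0),
                                population_floor=1e-7,
                                frequency_prefactor=False)
        mean = float(np.average(sticks.energies, weights=sticks.intensities))
        assert abs(mean - dmap.Evert) < 0.05 * 100.0


class TestReporting:
    def test_fundamental_fraction_origin_only(self):
        sticks = sticks_zero_T(displaced(0.0))
        assert fundamental_fraction(sticks) == (0.0, 0.0)

    def test_fundamental_fraction_poisson(self):
        limits = TruncationLimits(max_quanta=3, stick_floor=0.0,
                                  completeness_floor=0.0)
        sticks = sticks_zero_T(displaced(1.0), limits, frequency_prefactor=False)
        count_frac, int_frac = fundamental_fraction(sticks)
        assert count_frac == pytest.approx(1.0 / 4.0)
        total = sum(poisson_fc(1.0, n) for n in range(4))
        assert int_frac == pytest.approx(poisson_fc(1.0, 1) / total, rel=1e-9)

    def test_fundamental_fraction_two_mode(self):
        spec = ModelChromophoreSpec(freqs_initial=[1000.0, 1300.0],
                                    huang_rhys=[1.0, 0.5], E00=18000.0)
        limits = TruncationLimits(max_quanta=2, max_simultaneous=2,
                                  stick_floor=0.0, completeness_floor=0.0)
        sticks = sticks_zero_T(make_displaced_oscillators(spec), limits)
        is_fund = (sticks.init_quanta.sum(axis=1) == 0) & \
                  (sticks.final_quanta.sum(axis=1) == 1)
        assert is_fund.sum() == 2
        assert len(sticks) == 9

    def test_report_poisson_tie(self, poisson_map):
        sticks = sticks_zero_T(poisson_map, TruncationLimits(max_quanta=8),
                               frequency_prefactor=False)
        rows = assignment_report(sticks, top_n=3)
        # 0-0 and 0-1 tie exactly; lower energy wins
        assert rows[0]["label"] == "0-0"
        assert rows[1]["label"] == "1^1"
        assert rows[0]["intensity"] == pytest.approx(rows[1]["intensity"],
                                                     rel=1e-12)

    def test_report_origin_only(self):
        sticks = sticks_zero_T(displaced(0.0))
        rows = assignment_report(sticks, top_n=5)
        assert len(rows) == 1
        assert rows[0]["label"] == "0-0"

    def test_cy3_like_top_bands_involve_soft_mode(self):
        dmap = make_cy3_like([1.2, 0.05, 0.12, 0.1, 0.1, 0.15])
        sticks = sticks_zero_T(dmap, TruncationLimits(max_quanta=6,
                                                      max_simultaneous=3),
                               frequency_prefactor=False)
        rows = assignment_report(sticks, top_n=10, one_based=False)
        combos = [r for r in rows if sum(1 for q in r["final_quanta"] if q) > 1]
        assert combos, "expected combination bands among the top assignments"
        assert all(r["final_quanta"][0] > 0 for r in combos)

    def test_zero_based_labels(self, poisson_map):
        sticks = sticks_zero_T(poisson_map, TruncationLimits(max_quanta=3))
        rows = assignment_report(sticks, top_n=4, one_based=False)
        labels = {r["label"] for r in rows}
        assert "0^1" in labels
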