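import math

import numpy as np
import pytest

from vibronic.core_io import ElectronicStateBundle
from vibronic.model_systems import (
    ModelChromophoreSpec, make_displaced_oscillators, make_duschinsky_rotated,
)
from vibronic.vibronic_models import DuschinskyMap


@pytest.fixture
def diatomic_bundle() -> ElectronicStateBundle:
    """Homonuclear diatomic, 1 amu masses, k tuned to ~1000 cm^-1."""
    k = 1.8923e-2  # hartree/bohr^2
    h = np.zeros((6, 6))
    h[0, 0] = h[3, 3] = k
    h[0, 3] = h[3, 0] = -k
    return ElectronicStateBundle(
        label="diatomic", elements=["H", "H"],
        geometry=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        masses=np.array([1.0, 1.0]), energy=0.0, hessian=h)


@pytest.fixture
def displaced_map() -> DuschinskyMap:
    """Single displaced oscillator: S = 0.6, w = 1150 cm^-1, E00 = 18200."""
    spec = ModelChromophoreSpec(freqs_initial=[1150.0], huang_rhys=[0.6],
                                E00=18200.0)
    return make_displaced_oscillators(spec)


@pytest.fixture
def poisson_map() -> DuschinskyMap:
    """Single displaced oscillator with S = 1."""
    spec = ModelChromophoreSpec(freqs_initial=[1150.0], huang_rhys=[1.0],
                                E00=18200.0)
    return make_displaced_oscillators(spec)


def rotated_test_map(nmodes: int = 2, angle: float = 25.0,
                     displacements=(10.0, -6.0, 4.0, -3.0)) -> DuschinskyMap:
    """Hand-built Duschinsky map with rotation + displacement + freq change."""
    freqs_i = np.array([1000.0, 1400.0, 700.0, 1800.0])[:nmodes]
    freqs_f = np.array([1100.0, 1300.0, 800.0, 1700.0])[:nmodes]
    th = math.radians(angle)
    j = np.eye(nmodes)
    j2 = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    j[:2, :2] = j2
    if nmodes >= 4:  # mix a second pair so all modes rotate
        g = np.eye(nmodes)
        g[2:4, 2:4] = np.array([[math.cos(th / 2), -math.sin(th / 2)],
                                [math.sin(th / 2), math.cos(th / 2)]])
        j = j @ g
    k = np.asarray(displacements[:nmodes], float)
    e00 = 18200.0
    dmap = DuschinskyMap("AH", j, k, freqs_i, freqs_f, e00, e00)
    lam = 0.5 * float(k @ dmap.final_curvature_matrix() @ k) * 219474.6313632
    dmap.Evert = e00 + lam
    return dmap


@pytest.fixture
def duschinsky_2mode() -> DuschinskyMap:
    return rotated_test_map(2)


@pytest.fixture
def duschinsky_3mode() -> DuschinskyMap:
    return rotated_test_map(3)


@pytest.fixture
def rotated_bundles():
    spec = ModelChromophoreSpec(freqs_initial=[1000.0, 1400.0],
                                freqs_final=[1050.0, 1350.0],
                                rotation_angles=[(0, 1, 30.0)])
    return spec, make_duschinsky_rotated(spec, seed=0)
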