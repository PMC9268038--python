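"""Independent oracles used by the test suite.

These deliberately avoid the package's recursion/FFT code paths: FC factors
come from closed forms or direct Gauss-Hermite quadrature of the explicit
wavefunction product, and correlation functions from explicit sums over
stick spectra.
"""

from __future__ import annotations

import math


import numpy as np
import scipy.special
from numpy.polynomial.hermite import hermgauss

HARTREE_TO_CM = 219474.6313632


def poisson_fc(s: float, n: int) -> float:
    """0 -> n FC factor of a displaced oscillator with Huang-Rhys S."""
    return math.exp(-s) * s ** n / math.factorial(n)


def freq_change_00(w: float, wp: float) -> float:
    """0-0 FC factor for a pure frequency change (any consistent units)."""
    return 2.0 * math.sqrt(w * wp) / (w + wp)


def quadrature_overlap(dmap, v, vp, nodes: int = 48) -> float:
    """<v|v'> by tensor-product Gauss-Hermite quadrature of the explicit
    harmonic wavefunction product under the map's (J, K)."""
    w = np.asarray(dmap.freqs_initial, float) / HARTREE_TO_CM
    wp = np.asarray(dmap.freqs_final, float) / HARTREE_TO_CM
    j = np.asarray(dmap.J, float)
    k = np.asarray(dmap.K, float)
    n = w.size
    a = np.diag(w) + j.T @ np.diag(wp) @ j
    q0 = np.linalg.solve(a, j.T @ (np.diag(wp) @ (j @ k)))
    evals, u = np.linalg.eigh(a)
    scale = np.sqrt(2.0 / evals)
    x, wq = hermgauss(nodes)
    norm_i = [(w[i] / np.pi) ** 0.25 / math.sqrt(2.0 ** v[i] * math.factorial(v[i]))
              for i in range(n)]
    norm_f = [(wp[i] / np.pi) ** 0.25 / math.sqrt(2.0 ** vp[i] * math.factorial(vp[i]))
              for i in range(n)]
    # tensor grid, fully vectorized
    grids = np.meshgrid(*([x] * n), indexing="ij")
    xs = np.stack([g.ravel() for g in grids], axis=1)          # (nodes^n, n)
    wgrids = np.meshgrid(*([wq] * n), indexing="ij")
    weights = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
    q = q0[None, :] + xs @ (u * scale[None, :]).T
    qi = np.sqrt(w)[None, :] * q
    qf = np.sqrt(wp)[None, :] * ((q - k[None, :]) @ j.T)
    vals = np.ones(xs.shape[0])
    for i in range(n):
        vals *= norm_i[i] * scipy.special.eval_hermite(v[i], qi[:, i])
        vals *= norm_f[i] * scipy.special.eval_hermite(vp[i], qf[:, i])
    expo = np.exp(-0.5 * (qi ** 2).sum(1) - 0.5 * (qf ** 2).sum(1)
                  + (xs ** 2).sum(1))
    total = float((weights * vals * expo).sum())
    return total * float(np.prod(scale))


def correlation_from_sticks(sticks, times: np.ndarray) -> np.ndarray:
    """chi(t) = sum_k I_k exp(-i E_k t) from a (prefactor-free) stick list."""
    e_au = np.asarray(sticks.energies, float) / HARTREE_TO_CM
    weights = np.asarray(sticks.intensities, float)
    return (weights[None, :] * np.exp(-1j * np.outer(times, e_au))).sum(axis=1)


def gaussian(grid: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((grid - center) ** 2) / (2.0 * sigma ** 2))
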