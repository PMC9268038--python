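"""Nuclear-ensemble absorption spectra from harmonic sampling.

Ground-state geometries are drawn either from the Wigner distribution of
the vibrational ground/thermal state (quantum sampling) or from the
classical Boltzmann distribution of the same harmonic surface (an explicit
harmonic surrogate for MD-ensemble statistics).  Vertical excitation
energies are then evaluated on the analytic harmonic final surface, and
the spectrum is a Gaussian-convoluted sum of sticks, one per sample.

Real excitation tables (e.g. from QM/MM runs) can be injected as a records
CSV for the convolution and convergence operations.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core_io import (
    HARTREE_TO_CM, KB_CM_PER_K, Spectrum, TransitionRecord,
    ValidationError, rng_from_seed,
)
from .harmonic_analysis import NormalModeBasis
from .spectra_tools import spectral_distance
from .vibronic_models import DuschinskyMap

__all__ = [
    "EnsembleSamples", "wigner_sample", "classical_sample",
    "vertical_excitations", "nuclear_ensemble_spectrum", "convergence_series",
    "wigner_variance_au", "classical_variance_au",
    "read_records_csv", "write_records_csv",
]

FreqSource = Union[NormalModeBasis, DuschinskyMap, Sequence[float], np.ndarray]


@dataclass
class EnsembleSamples:
    """A batch of normal-coordinate samples (mass-weighted a.u.).

    ``displacements`` is (n, nvib); ``momenta`` is present for Wigner
    sampling only.  Cartesian geometries are derived on demand when the
    originating basis carries a reference geometry.
    """

    displacements: np.ndarray
    frequencies_cm: np.ndarray
    method: str
    temperature_K: float
    seed: Optional[int]
    momenta: Optional[np.ndarray] = None
    basis: Optional[NormalModeBasis] = None

    def __len__(self) -> int:
        return self.displacements.shape[0]

    def geometries(self) -> np.ndarray:
        """(n, natoms, 3) Cartesian geometries in Angstrom."""
        if self.basis is None:
            raise ValidationError("samples were drawn from frequencies only; "
                                  "no Cartesian reference available")
        ref = self.basis.reference_geometry
        return np.array([ref + self.basis.cartesian_displacement(q)
                         for q in self.displacements])


def _frequencies_cm(source: FreqSource) -> tuple[np.ndarray, Optional[NormalModeBasis]]:
    if isinstance(source, NormalModeBasis):
        return source.frequencies, source
    if isinstance(source, DuschinskyMap):
        return source.freqs_initial, None
    return np.asarray(source, dtype=float).reshape(-1), None


def wigner_variance_au(freq_cm: np.ndarray, T: float) -> np.ndarray:
    """Coordinate variance of the Wigner distribution: (1/2w) coth(w/2kBT)."""
    w_au = np.asarray(freq_cm, dtype=float) / HARTREE_TO_CM
    base = 1.0 / (2.0 * w_au)
    if T == 0:
        return base
    x = np.asarray(freq_cm, dtype=float) / (2.0 * KB_CM_PER_K * T)
    return base / np.tanh(x)


def classical_variance_au(freq_cm: np.ndarray, T: float) -> np.ndarray:
    """Coordinate variance of the classical Boltzmann distribution: kBT/w^2."""
    w_au = np.asarray(freq_cm, dtype=float) / HARTREE_TO_CM
    kt_au = KB_CM_PER_K * T / HARTREE_TO_CM
    return kt_au / w_au ** 2


def wigner_sample(source: FreqSource, T: float, n: int,
                  seed: Optional[int] = None,
                  *, with_momenta: bool = False) -> EnsembleSamples:
    """Draw n geometries from the harmonic Wigner distribution at T (K).

    T = 0 samples the zero-point (vibrational ground state) distribution.
    Momenta, when requested, carry variance (w/2) coth(w/2kBT).
    """
    freqs, basis = _frequencies_cm(source)
    if np.any(freqs <= 0):
        raise ValidationError("Wigner sampling requires all-positive frequencies")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if T < 0:
        raise ValidationError("temperature must be nonnegative")
    rng = rng_from_seed(seed)
    var_q = wigner_variance_au(freqs, T)
    disp = rng.standard_normal((n, freqs.size)) * np.sqrt(var_q)
    momenta = None
    if with_momenta:
        w_au = freqs / HARTREE_TO_CM
        var_p = var_q * w_au ** 2  # (w/2) coth(w / 2 kB T)
        momenta = rng.standard_normal((n, freqs.size)) * np.sqrt(var_p)
    return EnsembleSamples(disp, freqs, "wigner", float(T), seed, momenta, basis)


def classical_sample(source: FreqSource, T: float, n: int,
                     seed: Optional[int] = None) -> EnsembleSamples:
    """Draw n geometries from the classical harmonic Boltzmann distribution."""
    freqs, basis = _frequencies_cm(source)
    if np.any(freqs <= 0):
        raise ValidationError("classical sampling requires all-positive frequencies")
    if T <= 0:
        raise ValidationError("classical sampling requires T > 0")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = rng_from_seed(seed)
    disp = rng.standard_normal((n, freqs.size)) * np.sqrt(classical_variance_au(freqs, T))
    return EnsembleSamples(disp, freqs, "classical", float(T), seed, None, basis)


def vertical_excitations(samples: EnsembleSamples,
                         dmap: DuschinskyMap) -> list[TransitionRecord]:
    """Vertical gaps dE(Q) = E00 + V'(Q) - V(Q) on the harmonic surfaces.

    Under the Condon approximation the oscillator strength follows
    f = (2/3) dE |mu|^2 in atomic units.
    """
    if samples.displacements.shape[1] != dmap.nvib:
        raise ValidationError("sample dimension does not match the map")
    q = samples.displacements
    de_cm = np.atleast_1d(dmap.final_potential(q)) - np.atleast_1d(dmap.initial_potential(q))
    mu2 = dmap.dipole_strength
    f = (2.0 / 3.0) * (de_cm / HARTREE_TO_CM) * mu2
    f = np.clip(f, 0.0, None)
    return [TransitionRecord(float(e), float(ff), i)
            for i, (e, ff) in enumerate(zip(de_cm, f))]


def nuclear_ensemble_spectrum(records: Sequence[TransitionRecord], sigma: float,
                              grid: np.ndarray) -> Spectrum:
    """Gaussian-convoluted sum over vertical excitations.

    eps(v) = sum_i f_i exp(-(v - v_i)^2 / 2 sigma^2); conventional defaults
    are sigma = 250 cm^-1 for MD-style records and 500 cm^-1 for Wigner
    ensembles.
    """
    if not records:
        raise ValidationError("nuclear_ensemble_spectrum requires records")
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    grid = np.asarray(grid, dtype=float)
    energies = np.array([r.excitation_energy for r in records])
    strengths = np.array([r.oscillator_strength for r in records])
    if grid[0] > energies.min() - 4 * sigma or grid[-1] < energies.max() + 4 * sigma:
        warnings.warn("grid does not cover all records +- 4 sigma; spectrum "
                      "will be truncated", stacklevel=2)
    values = np.zeros_like(grid)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for e, s in zip(energies, strengths):
        values += s * np.exp(-(grid - e) ** 2 * inv2s2)
    meta = {"scheme": "ensemble", "broadening_convention": "sigma",
            "broadening_cm1": float(sigma), "n_records": len(records),
            "shift_applied_cm1": 0.0}
    return Spectrum(grid, values, meta)


def convergence_series(records: Sequence[TransitionRecord],
                       sizes: Sequence[int], sigma: float, grid: np.ndarray,
                       seed: Optional[int] = None) -> tuple[list[Spectrum], list[float]]:
    """Spectra from seeded random subsets of increasing size, plus the
    successive peak-normalized L1 distances between them.

    Subsets are nested prefixes of one seeded shuffle, mirroring how an
    ensemble grows as more frames are accumulated.
    """
    if max(sizes) > len(records):
        raise ValidationError("subset size exceeds the number of records")
    rng = rng_from_seed(seed)
    order = rng.permutation(len(records))
    spectra = []
    for size in sizes:
        subset = [records[i] for i in order[:size]]
        spectra.append(nuclear_ensemble_spectrum(subset, sigma, grid))
    distances = [spectral_distance(a, b)["l1"]
                 for a, b in zip(spectra, spectra[1:])]
    return spectra, distances


# -- records CSV: excitation_cm1,oscillator_strength ------------------------

def write_records_csv(records: Sequence[TransitionRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["excitation_cm1", "oscillator_strength"])
        for r in records:
            writer.writerow([repr(r.excitation_energy), repr(r.oscillator_strength)])


def read_records_csv(path) -> list[TransitionRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                "excitation_cm1" not in reader.fieldnames or \
                "oscillator_strength" not in reader.fieldnames:
            raise ValidationError(f"{path}: expected columns "
                                  "excitation_cm1,oscillator_strength")
        for i, row in enumerate(reader):
            records.append(TransitionRecord(float(row["excitation_cm1"]),
                                            float(row["oscillator_strength"]), i))
    return records
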