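"""Analytic model chromophores for exercising every engine without any
quantum-chemistry run.

Provides displaced-oscillator maps (the canonical Poisson oracle system),
Duschinsky-rotated bundle pairs that round-trip through the AH builder, a
six-mode model whose excited-state frequencies follow the printed values
for a cyanine chromophore (34.9, 354, 1136, 1378, 1415, 1525 cm^-1 --
displacement amplitudes are illustrative, not literature values), and
seeded random bundles with exact translation/rotation null spaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .core_io import (
    AMU_TO_ME, BOHR_TO_ANGSTROM, HARTREE_TO_CM,
    ElectronicStateBundle, ValidationError, rng_from_seed,
)
from .harmonic_analysis import tr_projection_basis
from .vibronic_models import DuschinskyMap, build_map

__all__ = [
    "ModelChromophoreSpec", "CY3_LIKE_FREQS_CM",
    "make_displaced_oscillators", "make_duschinsky_rotated",
    "make_cy3_like", "make_random_bundle",
]

# Printed excited-state frequencies of the six most active modes of the
# cyanine model (cm^-1); amplitudes are free parameters of the fixture.
CY3_LIKE_FREQS_CM = (34.9, 354.0, 1136.0, 1378.0, 1415.0, 1525.0)


@dataclass
class ModelChromophoreSpec:
    """Declarative description of an analytic harmonic chromophore."""

    freqs_initial: Sequence[float]                  # cm^-1
    freqs_final: Optional[Sequence[float]] = None   # defaults to initial
    huang_rhys: Optional[Sequence[float]] = None    # S >= 0, per mode
    displacements: Optional[Sequence[float]] = None # K (a.u.), alternative to S
    rotation_angles: Sequence[tuple[int, int, float]] = field(default_factory=list)
    E00: float = 18200.0                            # cm^-1
    transition_dipole: Sequence[float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.freqs_initial = np.asarray(self.freqs_initial, dtype=float)
        self.freqs_final = (self.freqs_initial.copy() if self.freqs_final is None
                            else np.asarray(self.freqs_final, dtype=float))
        if self.freqs_final.size != self.freqs_initial.size:
            raise ValidationError("initial/final frequency counts differ")
        if self.huang_rhys is not None and self.displacements is not None:
            raise ValidationError("give huang_rhys or displacements, not both")
        if self.huang_rhys is not None:
            self.huang_rhys = np.asarray(self.huang_rhys, dtype=float)
            if np.any(self.huang_rhys < 0):
                raise ValidationError("Huang-Rhys factors must be nonnegative")
        if self.displacements is not None:
            self.displacements = np.asarray(self.displacements, dtype=float)
        for i, j, theta in self.rotation_angles:
            if not -90.0 < theta < 90.0:
                raise ValidationError("rotation angles must lie in (-90, 90) degrees")
            if i == j:
                raise ValidationError("rotation pair indices must differ")

    @property
    def nmodes(self) -> int:
        return self.freqs_initial.size

    def displacement_vector(self) -> np.ndarray:
        """K in mass-weighted a.u.; from S via K_i = sqrt(2 S_i / w_i)."""
        if self.displacements is not None:
            return self.displacements.copy()
        if self.huang_rhys is None:
            return np.zeros(self.nmodes)
        w_au = self.freqs_initial / HARTREE_TO_CM
        return np.sqrt(2.0 * self.huang_rhys / w_au)

    def rotation_matrix(self) -> np.ndarray:
        r = np.eye(self.nmodes)
        for i, j, theta in self.rotation_angles:
            g = np.eye(self.nmodes)
            c, s = math.cos(math.radians(theta)), math.sin(math.radians(theta))
            g[i, i] = g[j, j] = c
            g[i, j] = -s
            g[j, i] = s
            r = g @ r
        return r


def make_displaced_oscillators(spec: ModelChromophoreSpec) -> DuschinskyMap:
    """J = I map with per-mode displacements; Evert = E00 + sum(S_i w_i)
    when the frequencies are unchanged."""
    k = spec.displacement_vector()
    wp_au = spec.freqs_final / HARTREE_TO_CM
    lam_cm = 0.5 * float(np.sum(wp_au ** 2 * k ** 2)) * HARTREE_TO_CM
    return DuschinskyMap(
        model="AS", J=np.eye(spec.nmodes), K=k,
        freqs_initial=spec.freqs_initial, freqs_final=spec.freqs_final,
        E00=spec.E00, Evert=spec.E00 + lam_cm,
        transition_dipole=np.asarray(spec.transition_dipole, dtype=float))


def make_cy3_like(huang_rhys: Sequence[float],
                  E00: float = 18200.0) -> DuschinskyMap:
    """Six-mode cyanine-like model on the printed excited-state frequencies.

    ``huang_rhys`` supplies the six illustrative displacement amplitudes
    (modes are indexed 0-5 here, ordered by frequency).
    """
    s = np.asarray(huang_rhys, dtype=float)
    if s.size != 6:
        raise ValidationError("the cyanine-like model takes exactly 6 S values")
    spec = ModelChromophoreSpec(freqs_initial=CY3_LIKE_FREQS_CM,
                                huang_rhys=s, E00=E00)
    return make_displaced_oscillators(spec)


# ---------------------------------------------------------------------------
# Cartesian bundle emission
# ---------------------------------------------------------------------------

def _reference_frame(nmodes: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic nonlinear scaffold with 3N-6 >= nmodes vibrations."""
    natoms = max(3, math.ceil((nmodes + 6) / 3))
    rng = rng_from_seed(seed)
    while True:
        geom = rng.normal(scale=1.2, size=(natoms, 3))  # Angstrom
        # reject nearly-collinear draws so the TR space is 6-dimensional
        centered = geom - geom.mean(axis=0)
        svals = np.linalg.svd(centered, compute_uv=False)
        if svals[1] > 0.3:
            break
    masses = np.full(natoms, 12.0)
    comp = scipy.linalg.null_space(
        tr_projection_basis(geom / BOHR_TO_ANGSTROM, masses * AMU_TO_ME).T)
    return geom, masses, comp


def _bundle_from_modes(label: str, geom: np.ndarray, masses: np.ndarray,
                       modes: np.ndarray, freqs_cm: np.ndarray, energy_h: float,
                       dipole: Optional[np.ndarray]) -> ElectronicStateBundle:
    w2 = (np.asarray(freqs_cm, dtype=float) / HARTREE_TO_CM) ** 2
    h_mw = modes @ (w2[:, None] * modes.T)
    sqrt_m = np.sqrt(np.repeat(masses * AMU_TO_ME, 3))
    hessian = h_mw * np.outer(sqrt_m, sqrt_m)
    return ElectronicStateBundle(
        label=label, elements=["C"] * len(masses), geometry=geom,
        masses=masses, energy=energy_h, hessian=hessian,
        transition_dipole=dipole)


def make_duschinsky_rotated(spec: ModelChromophoreSpec, seed: int = 0
                            ) -> tuple[DuschinskyMap, ElectronicStateBundle,
                                       ElectronicStateBundle]:
    """Bundle pair whose AH map realizes the requested mode rotation.

    Spec frequencies are padded with high-frequency spectator modes up to
    the scaffold's 3N-6.  Displacements are applied along the initial
    modes; note that displacing a rotated fixture introduces a small
    Eckart-frame (axis-switching) mismatch, so exact round-tripping holds
    for the undisplaced case.  The returned map is the one built by
    :func:`vibronic_models.build_map` on the emitted bundles, so map and
    bundles are consistent by construction.
    """
    if spec.nmodes < 2:
        raise ValidationError("a rotated fixture needs at least 2 modes")
    geom, masses, comp = _reference_frame(spec.nmodes, seed)
    nvib = comp.shape[1]
    pad = nvib - spec.nmodes
    top = float(max(spec.freqs_initial.max(), spec.freqs_final.max()))
    pad_freqs = top + 1500.0 + 200.0 * np.arange(pad)
    w_i = np.concatenate([spec.freqs_initial, pad_freqs])
    w_f = np.concatenate([spec.freqs_final, pad_freqs])

    r_full = np.eye(nvib)
    r_full[:spec.nmodes, :spec.nmodes] = spec.rotation_matrix()
    modes_i = comp
    modes_f = modes_i @ r_full.T   # J = L_f^T L_i = R

    k = np.concatenate([spec.displacement_vector(), np.zeros(pad)])
    sqrt_m = np.sqrt(np.repeat(masses * AMU_TO_ME, 3))
    dx_bohr = (modes_i @ k) / sqrt_m
    geom_f = geom + dx_bohr.reshape(-1, 3) * BOHR_TO_ANGSTROM

    e00_h = spec.E00 / HARTREE_TO_CM
    dipole = np.asarray(spec.transition_dipole, dtype=float)
    initial = _bundle_from_modes("ground", geom, masses, modes_i, w_i, 0.0, None)
    final = _bundle_from_modes("excited", geom_f, masses, modes_f, w_f, e00_h, dipole)
    dmap = build_map(initial, final, "AH")
    # The mode-phase convention of normal_modes may flip eigenvector signs
    # relative to the generating basis; undo that gauge so the returned map
    # carries exactly the requested rotation.  FC intensities are invariant.
    from .harmonic_analysis import normal_modes
    d_i = np.sign(np.diag(normal_modes(initial).modes.T @ modes_i))
    d_f = np.sign(np.diag(normal_modes(final).modes.T @ modes_f))
    dmap = DuschinskyMap(
        model="AH", J=d_f[:, None] * dmap.J * d_i[None, :], K=d_i * dmap.K,
        freqs_initial=dmap.freqs_initial, freqs_final=dmap.freqs_final,
        E00=dmap.E00, Evert=dmap.Evert, transition_dipole=dmap.transition_dipole)
    return dmap, initial, final


def make_random_bundle(natoms: int, seed: Optional[int] = None) -> ElectronicStateBundle:
    """Seeded random bundle with a positive-definite vibrational Hessian
    and an exact translation/rotation null space."""
    if natoms < 3:
        raise ValidationError("make_random_bundle needs natoms >= 3")
    rng = rng_from_seed(seed)
    while True:
        geom = rng.normal(scale=1.5, size=(natoms, 3))
        centered = geom - geom.mean(axis=0)
        if np.linalg.svd(centered, compute_uv=False)[1] > 0.3:
            break
    masses = rng.uniform(1.0, 16.0, size=natoms)
    comp = scipy.linalg.null_space(
        tr_projection_basis(geom / BOHR_TO_ANGSTROM, masses * AMU_TO_ME).T)
    nvib = comp.shape[1]
    freqs = np.sort(rng.uniform(300.0, 3000.0, size=nvib))
    # random orthogonal mixing inside the vibrational subspace
    q, _ = np.linalg.qr(rng.normal(size=(nvib, nvib)))
    modes = comp @ q
    return _bundle_from_modes(f"random-{natoms}", geom, masses, modes, freqs,
                              0.0, None)
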