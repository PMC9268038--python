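"""Normal-mode analysis of Cartesian Hessians.

Mass-weighting, Eckart translation/rotation projection, diagonalization in
the vibrational subspace, and projection of Cartesian gradients onto
normal coordinates.  All heavy lifting happens in atomic units; frequencies
cross the interface in cm^-1 with imaginary modes encoded as negative
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core_io import (
    AMU_TO_ME, BOHR_TO_ANGSTROM, HARTREE_TO_CM,
    ElectronicStateBundle, ValidationError,
)

__all__ = ["NormalModeBasis", "normal_modes", "project_gradient", "tr_projection_basis"]

_LINEAR_INERTIA_THRESHOLD = 1e-10  # amu * Angstrom^2


@dataclass
class NormalModeBasis:
    """Vibrational eigenbasis of a mass-weighted, TR-projected Hessian.

    ``modes`` is 3N x Nvib with orthonormal columns in mass-weighted
    Cartesian space; ``frequencies`` are sorted ascending in cm^-1
    (negative encodes imaginary).
    """

    frequencies: np.ndarray          # (nvib,), cm^-1
    modes: np.ndarray                # (3N, nvib), mass-weighted orthonormal
    reference_geometry: np.ndarray   # (natoms, 3), Angstrom
    masses: np.ndarray               # (natoms,), amu
    nvib: int

    @property
    def natoms(self) -> int:
        return len(self.masses)

    @property
    def frequencies_au(self) -> np.ndarray:
        """Signed angular frequencies in atomic units."""
        return self.frequencies / HARTREE_TO_CM

    def cartesian_displacement(self, q: np.ndarray) -> np.ndarray:
        """Map normal coordinates (mass-weighted a.u.) to Cartesian Angstrom offsets."""
        q = np.asarray(q, dtype=float)
        dx_mw = self.modes @ q                       # mass-weighted bohr
        inv_sqrt_m = 1.0 / np.sqrt(np.repeat(self.masses * AMU_TO_ME, 3))
        return (dx_mw * inv_sqrt_m).reshape(-1, 3) * BOHR_TO_ANGSTROM


def _is_linear(geometry_bohr: np.ndarray, masses_amu: np.ndarray) -> bool:
    com = np.average(geometry_bohr, axis=0, weights=masses_amu)
    x = geometry_bohr - com
    inertia = np.zeros((3, 3))
    for m, r in zip(masses_amu, x):
        inertia += m * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    eigvals = np.linalg.eigvalsh(inertia) * BOHR_TO_ANGSTROM ** 2
    return bool(eigvals[0] < _LINEAR_INERTIA_THRESHOLD)


def tr_projection_basis(geometry_bohr: np.ndarray, masses_me: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 3N-dim translation+rotation subspace.

    Built in mass-weighted coordinates from the Eckart conditions at the
    reference geometry; returns a 3N x (5 or 6) matrix.
    """
    n = len(masses_me)
    sqrt_m = np.sqrt(masses_me)
    com = np.average(geometry_bohr, axis=0, weights=masses_me)
    x = geometry_bohr - com
    vecs = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = sqrt_m
        vecs.append(t.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        r = np.cross(x, e) * sqrt_m[:, None]
        vecs.append(r.ravel())
    raw = np.column_stack(vecs)
    # Orthonormalize; drop null rotations (linear molecules) by singular value.
    u, s, _ = np.linalg.svd(raw, full_matrices=False)
    keep = s > 1e-8 * s[0]
    return u[:, keep]


def normal_modes(bundle: ElectronicStateBundle) -> NormalModeBasis:
    """Mass-weighted normal-mode analysis with Eckart TR projection.

    Translations and rotations are projected out before diagonalization,
    so exactly 3N-6 (3N-5 if linear) vibrations are returned.  Eigenvector
    phases are fixed by making each mode's largest-magnitude component
    positive.
    """
    if bundle.hessian is None:
        raise ValidationError("normal_modes requires a bundle with a Hessian")
    masses_me = bundle.masses_me
    if masses_me.sum() < 1e-6:
        raise ValidationError("total mass is near zero")
    geometry_bohr = bundle.geometry_bohr
    n = bundle.natoms

    sqrt_m = np.sqrt(np.repeat(masses_me, 3))
    h_mw = bundle.hessian / np.outer(sqrt_m, sqrt_m)

    tr = tr_projection_basis(geometry_bohr, masses_me)
    linear = _is_linear(geometry_bohr, bundle.masses)
    nvib_expected = 3 * n - (5 if linear else 6)
    if tr.shape[1] != 3 * n - nvib_expected:
        raise ValidationError(
            f"TR subspace dimension {tr.shape[1]} inconsistent with detected "
            f"{'linear' if linear else 'nonlinear'} geometry")

    # Complement of the TR space: diagonalize in the vibrational subspace only.
    comp = scipy.linalg.null_space(tr.T)
    if comp.shape[1] != nvib_expected:
        raise ValidationError("vibrational subspace dimension mismatch")
    h_vib = comp.T @ h_mw @ comp
    h_vib = 0.5 * (h_vib + h_vib.T)
    eigvals, eigvecs = np.linalg.eigh(h_vib)
    modes = comp @ eigvecs

    freqs_au = np.sign(eigvals) * np.sqrt(np.abs(eigvals))
    freqs_cm = freqs_au * HARTREE_TO_CM
    order = np.argsort(freqs_cm, kind="stable")
    freqs_cm = freqs_cm[order]
    modes = modes[:, order]

    # Deterministic phase: largest-|component| positive.
    for j in range(modes.shape[1]):
        k = int(np.argmax(np.abs(modes[:, j])))
        if modes[k, j] < 0:
            modes[:, j] = -modes[:, j]

    return NormalModeBasis(
        frequencies=freqs_cm,
        modes=modes,
        reference_geometry=bundle.geometry.copy(),
        masses=bundle.masses.copy(),
        nvib=nvib_expected,
    )


def project_gradient(bundle: ElectronicStateBundle, basis: NormalModeBasis) -> np.ndarray:
    """Project a Cartesian gradient onto mass-weighted normal coordinates.

    g_Q = L^T M^(-1/2) g_cart, in atomic units; length Nvib.
    """
    if bundle.gradient is None:
        raise ValidationError("project_gradient requires a bundle with a gradient")
    if bundle.natoms != basis.natoms:
        raise ValidationError("bundle and basis atom counts differ")
    if bundle.gradient.size != basis.modes.shape[0]:
        raise ValidationError("gradient dimension does not match the mode basis")
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(bundle.masses_me, 3))
    return basis.modes.T @ (bundle.gradient * inv_sqrt_m)
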