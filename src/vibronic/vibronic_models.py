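"""Harmonic final-state surface construction: AH, AS, VH and VG maps.

The final electronic state's potential is expressed in the initial state's
mass-weighted normal coordinates Q as

    V'(Q) = E00 + 1/2 (Q - K)^T  J^T diag(w'^2) J  (Q - K)

with J the Duschinsky rotation (final modes in the initial mode basis,
J = L_f^T L_i) and K the final-state minimum position in initial normal
coordinates (mass-weighted atomic units).  Final normal coordinates are
Q' = J (Q - K).

The four builders differ only in what they require and how they obtain
(J, K, w'):

* AH — final minimum geometry and Hessian; full rotation + displacement.
* AS — final minimum geometry; J = I and the initial frequencies reused.
* VH — final Hessian + gradient at the initial minimum; rotation from the
  vertical Hessian, minimum extrapolated from the gradient.
* VG — final gradient at the initial minimum; J = I, K_i = -g_i / w_i^2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core_io import HARTREE_TO_CM, ElectronicStateBundle, ValidationError
from .harmonic_analysis import NormalModeBasis, normal_modes, project_gradient

__all__ = ["DuschinskyMap", "ModeActivity", "build_map", "mode_activity"]

logger = logging.getLogger(__name__)

_MODELS = ("AH", "AS", "VH", "VG")


@dataclass
class DuschinskyMap:
    """Final-state harmonic surface relative to the initial state."""

    model: str
    J: np.ndarray                 # (nvib, nvib)
    K: np.ndarray                 # (nvib,), mass-weighted a.u.
    freqs_initial: np.ndarray     # cm^-1
    freqs_final: np.ndarray       # cm^-1
    E00: float                    # cm^-1, electronic-minimum gap (no ZPE)
    Evert: float                  # cm^-1, vertical gap at the initial minimum
    transition_dipole: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        self.K = np.asarray(self.K, dtype=float).reshape(-1)
        self.freqs_initial = np.asarray(self.freqs_initial, dtype=float).reshape(-1)
        self.freqs_final = np.asarray(self.freqs_final, dtype=float).reshape(-1)
        self.transition_dipole = np.asarray(self.transition_dipole, dtype=float).reshape(3)
        n = self.nvib
        if self.J.shape != (n, n):
            raise ValidationError(f"J must be {n}x{n}, got {self.J.shape}")
        if not (self.K.size == n and self.freqs_final.size == n):
            raise ValidationError("J, K and frequency arrays must agree in dimension")
        if self.model not in _MODELS:
            raise ValidationError(f"model must be one of {_MODELS}")
        dev = np.abs(self.J @ self.J.T - np.eye(n)).max()
        if dev > 1e-8:
            raise ValidationError(f"J is not orthogonal (max deviation {dev:.2e})")
        if self.model in ("AS", "VG") and np.abs(self.J - np.eye(n)).max() > 0:
            raise ValidationError(f"{self.model} requires J = identity exactly")

    @property
    def nvib(self) -> int:
        return self.freqs_initial.size

    @property
    def freqs_initial_au(self) -> np.ndarray:
        return self.freqs_initial / HARTREE_TO_CM

    @property
    def freqs_final_au(self) -> np.ndarray:
        return self.freqs_final / HARTREE_TO_CM

    @property
    def E00_zpe(self) -> float:
        """0-0 gap including the zero-point-energy difference (cm^-1)."""
        return self.E00 + 0.5 * float(np.sum(self.freqs_final - self.freqs_initial))

    @property
    def dipole_strength(self) -> float:
        """|mu|^2 in atomic units (Condon)."""
        return float(self.transition_dipole @ self.transition_dipole)

    def final_curvature_matrix(self) -> np.ndarray:
        """A = J^T diag(w'^2) J in atomic units."""
        w2 = self.freqs_final_au ** 2
        return self.J.T @ (w2[:, None] * self.J)

    def final_potential(self, q: np.ndarray) -> np.ndarray:
        """V'(Q) - electronic origin of the initial state, in cm^-1.

        ``q`` is (nvib,) or (nsamples, nvib) in mass-weighted a.u.
        """
        q = np.atleast_2d(np.asarray(q, dtype=float))
        dq = q - self.K
        a = self.final_curvature_matrix()
        quad = 0.5 * np.einsum("si,ij,sj->s", dq, a, dq) * HARTREE_TO_CM
        out = self.E00 + quad
        return out if out.size > 1 else float(out[0])

    def initial_potential(self, q: np.ndarray) -> np.ndarray:
        """V(Q) relative to the initial minimum, in cm^-1."""
        q = np.atleast_2d(np.asarray(q, dtype=float))
        w2 = self.freqs_initial_au ** 2
        out = 0.5 * np.sum(w2 * q * q, axis=1) * HARTREE_TO_CM
        return out if out.size > 1 else float(out[0])

    # -- structured-text export for inspection --
    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "J": self.J.tolist(),
            "K_au": self.K.tolist(),
            "freqs_initial_cm1": self.freqs_initial.tolist(),
            "freqs_final_cm1": self.freqs_final.tolist(),
            "E00_cm1": self.E00,
            "Evert_cm1": self.Evert,
            "transition_dipole_au": self.transition_dipole.tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "DuschinskyMap":
        doc = json.loads(Path(path).read_text())
        return cls(model=doc["model"], J=doc["J"], K=doc["K_au"],
                   freqs_initial=doc["freqs_initial_cm1"],
                   freqs_final=doc["freqs_final_cm1"],
                   E00=doc["E00_cm1"], Evert=doc["Evert_cm1"],
                   transition_dipole=doc["transition_dipole_au"])


@dataclass
class ModeActivity:
    """Per-mode Huang-Rhys factors and the total reorganization energy."""

    huang_rhys: np.ndarray        # dimensionless, per initial mode
    reorganization_cm1: float


def _displacement_in_initial_modes(initial: ElectronicStateBundle,
                                   final: ElectronicStateBundle,
                                   basis: NormalModeBasis) -> np.ndarray:
    """K = L_i^T M^(1/2) (x_final - x_initial), mass-weighted a.u."""
    sqrt_m = np.sqrt(np.repeat(initial.masses_me, 3))
    dx = (final.geometry_bohr - initial.geometry_bohr).ravel()
    return basis.modes.T @ (sqrt_m * dx)


def _dipole_from(final: ElectronicStateBundle, evert_au: float) -> np.ndarray:
    if final.transition_dipole is not None:
        return final.transition_dipole.copy()
    if final.oscillator_strength is not None and evert_au > 0:
        # f = (2/3) dE |mu|^2 (a.u.); direction information is lost.
        mu2 = 1.5 * final.oscillator_strength / evert_au
        return np.array([np.sqrt(mu2), 0.0, 0.0])
    return np.array([1.0, 0.0, 0.0])


def build_map(initial: ElectronicStateBundle,
              final: ElectronicStateBundle,
              model: str,
              *,
              initial_basis: Optional[NormalModeBasis] = None,
              drop_imaginary: bool = False) -> DuschinskyMap:
    """Build the final-state surface under one of the four harmonic models.

    ``final`` is interpreted per model: for AH/AS it holds the final-state
    minimum (geometry, energy, and for AH the Hessian); for VH/VG it holds
    vertical data evaluated at the initial minimum (energy, gradient, and
    for VH the Hessian).
    """
    model = model.upper()
    if model not in _MODELS:
        raise ValidationError(f"model must be one of {_MODELS}")
    if initial_basis is None:
        initial_basis = normal_modes(initial)
    basis = initial_basis
    w_au = basis.frequencies_au
    if np.any(w_au <= 0):
        raise ValidationError("initial-state frequencies must all be positive")

    if model == "AH":
        if final.hessian is None:
            raise ValidationError("AH requires the final-state Hessian at its minimum")
        basis_f = normal_modes(final)
        if basis_f.nvib != basis.nvib:
            raise ValidationError("initial and final vibrational dimensions differ")
        j = basis_f.modes.T @ basis.modes
        k = _displacement_in_initial_modes(initial, final, basis)
        wf = basis_f.frequencies
        j, wf, keep = _handle_imaginary(j, wf, drop_imaginary, model)
        k = k[keep]
        wi = basis.frequencies[keep]
        # Re-orthogonalize against TR-projection residuals between the two frames.
        u, _, vt = np.linalg.svd(j)
        j = u @ vt
        e00 = (final.energy - initial.energy) * HARTREE_TO_CM
        a = j.T @ (((wf / HARTREE_TO_CM) ** 2)[:, None] * j)
        evert = e00 + 0.5 * float(k @ a @ k) * HARTREE_TO_CM
        dip = _dipole_from(final, evert / HARTREE_TO_CM)
        return DuschinskyMap("AH", j, k, wi, wf, e00, evert, dip)

    if model == "AS":
        k = _displacement_in_initial_modes(initial, final, basis)
        e00 = (final.energy - initial.energy) * HARTREE_TO_CM
        lam_au = 0.5 * float(np.sum(w_au ** 2 * k ** 2))
        evert = e00 + lam_au * HARTREE_TO_CM
        dip = _dipole_from(final, evert / HARTREE_TO_CM)
        return DuschinskyMap("AS", np.eye(basis.nvib), k, basis.frequencies,
                             basis.frequencies.copy(), e00, evert, dip)

    # Vertical models: `final` evaluated at the initial minimum geometry.
    if np.abs(final.geometry - initial.geometry).max() > 1e-8:
        raise ValidationError(
            f"{model} requires final-state data evaluated at the initial geometry")
    evert = (final.energy - initial.energy) * HARTREE_TO_CM

    if model == "VG":
        if final.gradient is None:
            raise ValidationError("VG requires the final-state gradient")
        g_q = project_gradient(final, basis)
        k = -g_q / w_au ** 2
        lam_au = 0.5 * float(np.sum(w_au ** 2 * k ** 2))
        e00 = evert - lam_au * HARTREE_TO_CM
        dip = _dipole_from(final, evert / HARTREE_TO_CM)
        return DuschinskyMap("VG", np.eye(basis.nvib), k, basis.frequencies,
                             basis.frequencies.copy(), e00, evert, dip)

    # VH
    if final.hessian is None or final.gradient is None:
        raise ValidationError("VH requires the final-state Hessian and gradient")
    basis_f = normal_modes(final)
    if basis_f.nvib != basis.nvib:
        raise ValidationError("initial and final vibrational dimensions differ")
    j = basis_f.modes.T @ basis.modes
    wf = basis_f.frequencies
    j, wf, keep = _handle_imaginary(j, wf, drop_imaginary, model)
    u, _, vt = np.linalg.svd(j)
    j = u @ vt
    g_q = project_gradient(final, basis)[keep]
    a = j.T @ (((wf / HARTREE_TO_CM) ** 2)[:, None] * j)
    k = -np.linalg.solve(a, g_q)
    e00 = evert - 0.5 * float(k @ a @ k) * HARTREE_TO_CM
    dip = _dipole_from(final, evert / HARTREE_TO_CM)
    return DuschinskyMap("VH", j, k, basis.frequencies[keep], wf, e00, evert, dip)


def _handle_imaginary(j: np.ndarray, wf: np.ndarray, drop: bool,
                      model: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bad = wf <= 0
    if not bad.any():
        return j, wf, np.arange(j.shape[1])
    if not drop:
        raise ValidationError(
            f"{model} produced imaginary final frequencies "
            f"{wf[bad].round(2).tolist()} cm^-1; pass drop_imaginary=True to remove them")
    logger.warning("%s: dropping %d imaginary final mode(s): %s cm^-1",
                   model, int(bad.sum()), wf[bad].round(2).tolist())
    j = j[~bad, :]
    # Keep the map square: drop the initial modes carrying the least weight in
    # the retained rows; the caller re-orthogonalizes the remaining block.
    weights = np.abs(j).sum(axis=0)
    drop_cols = np.argsort(weights)[: int(bad.sum())]
    keep_cols = np.setdiff1d(np.arange(j.shape[1]), drop_cols)
    return j[:, keep_cols], wf[~bad], keep_cols


def mode_activity(dmap: DuschinskyMap) -> ModeActivity:
    """Huang-Rhys factors S_i = w_i K_i^2 / 2 (initial frequencies) and the
    reorganization energy lambda = Evert - E00 of the final surface."""
    s = 0.5 * dmap.freqs_initial_au * dmap.K ** 2
    lam = dmap.Evert - dmap.E00
    return ModeActivity(huang_rhys=s, reorganization_cm1=float(lam))
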