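"""Core domain types, unit conversions, and text-based file I/O.

Internal computations run in atomic units (hbar = 1); interfaces speak
Angstrom, amu, cm^-1 and eV.  The fixed constants below are the single
source of truth for every conversion in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HARTREE_TO_CM", "HARTREE_TO_EV", "EV_TO_CM", "KB_CM_PER_K",
    "AMU_TO_ME", "BOHR_TO_ANGSTROM", "NM_CM_PRODUCT",
    "ValidationError", "ParseError",
    "ElectronicStateBundle", "Spectrum", "TransitionRecord",
    "convert_energy", "read_bundle", "write_bundle",
    "read_spectrum", "write_spectrum", "read_xyz", "write_xyz",
    "rng_from_seed",
]

# Fixed conversion constants (CODATA-consistent; documented contract values).
HARTREE_TO_CM = 219474.6313632       # 1 hartree in cm^-1
HARTREE_TO_EV = 27.211386245988      # 1 hartree in eV
EV_TO_CM = HARTREE_TO_CM / HARTREE_TO_EV
KB_CM_PER_K = 0.695034800            # Boltzmann constant in cm^-1 / K
AMU_TO_ME = 1822.888486              # 1 amu in electron masses
BOHR_TO_ANGSTROM = 0.529177210903    # 1 bohr in Angstrom
NM_CM_PRODUCT = 1.0e7                # lambda[nm] * nu[cm^-1] = 1e7


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class ParseError(ValueError):
    """A file does not conform to its schema; message names the field."""


def rng_from_seed(seed: Optional[int]) -> np.random.Generator:
    """Package-wide RNG policy: NumPy PCG64 seeded explicitly.

    Every public operation that consumes randomness routes through this
    helper so identical seeds give identical outputs.
    """
    return np.random.Generator(np.random.PCG64(seed))


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

_ENERGY_UNITS = ("hartree", "eV", "cm-1", "nm")


def _to_cm(value: float, unit: str) -> float:
    if unit == "hartree":
        return value * HARTREE_TO_CM
    if unit == "eV":
        return value * EV_TO_CM
    if unit == "cm-1":
        return value
    if unit == "nm":
        if value <= 0:
            raise ValidationError("nm <-> energy conversion requires a positive value")
        return NM_CM_PRODUCT / value
    raise ValidationError(f"unknown energy unit {unit!r}; expected one of {_ENERGY_UNITS}")


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert energies among hartree, eV, cm-1 and (reciprocally) nm.

    Conversions are self-inverse to 1e-12 relative precision.
    """
    cm = _to_cm(float(value), from_unit)
    if to_unit == "hartree":
        return cm / HARTREE_TO_CM
    if to_unit == "eV":
        return cm / EV_TO_CM
    if to_unit == "cm-1":
        return cm
    if to_unit == "nm":
        if cm <= 0:
            raise ValidationError("nm <-> energy conversion requires a positive value")
        return NM_CM_PRODUCT / cm
    raise ValidationError(f"unknown energy unit {to_unit!r}; expected one of {_ENERGY_UNITS}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ElectronicStateBundle:
    """One electronic state's harmonic data.

    Units follow the on-disk schema: geometry in Angstrom, masses in amu,
    energy in hartree, Hessian in hartree/bohr^2, gradient in hartree/bohr,
    transition dipole in atomic units.
    """

    label: str
    elements: list[str]
    geometry: np.ndarray                      # (natoms, 3), Angstrom
    masses: np.ndarray                        # (natoms,), amu
    energy: float                             # hartree
    hessian: Optional[np.ndarray] = None      # (3N, 3N), hartree/bohr^2
    gradient: Optional[np.ndarray] = None     # (3N,), hartree/bohr
    transition_dipole: Optional[np.ndarray] = None  # (3,), a.u.
    oscillator_strength: Optional[float] = None

    def __post_init__(self) -> None:
        self.elements = [str(e) for e in self.elements]
        self.geometry = np.asarray(self.geometry, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = self.natoms
        if self.geometry.shape != (n, 3):
            raise ValidationError(
                f"geometry_angstrom: expected shape ({n}, 3), got {self.geometry.shape}")
        if self.masses.shape != (n,):
            raise ValidationError(f"masses_amu: expected {n} masses, got {self.masses.shape}")
        if np.any(self.masses <= 0):
            raise ValidationError("masses_amu: masses must be strictly positive")
        if self.hessian is not None:
            self.hessian = np.asarray(self.hessian, dtype=float)
            if self.hessian.shape != (3 * n, 3 * n):
                raise ValidationError(
                    f"hessian_hartree_bohr2: expected shape ({3*n}, {3*n}), "
                    f"got {self.hessian.shape}")
            scale = max(1.0, float(np.abs(self.hessian).max()))
            asym = float(np.abs(self.hessian - self.hessian.T).max())
            if asym > 1e-8 * scale:
                raise ValidationError(
                    f"hessian_hartree_bohr2: asymmetric beyond tolerance "
                    f"(max |H - H^T| = {asym:.3e})")
            self.hessian = 0.5 * (self.hessian + self.hessian.T)
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, dtype=float).reshape(-1)
            if self.gradient.shape != (3 * n,):
                raise ValidationError(
                    f"gradient_hartree_bohr: expected length {3*n}, got {self.gradient.shape}")
        if self.transition_dipole is not None:
            self.transition_dipole = np.asarray(self.transition_dipole, dtype=float)
            if self.transition_dipole.shape != (3,):
                raise ValidationError("transition_dipole_au: expected a 3-vector")
        if self.oscillator_strength is not None:
            self.oscillator_strength = float(self.oscillator_strength)
            if self.oscillator_strength < 0:
                raise ValidationError("oscillator_strength must be nonnegative")

    @property
    def natoms(self) -> int:
        return len(self.elements)

    # -- unit helpers (internal atomic-unit views) --
    @property
    def geometry_bohr(self) -> np.ndarray:
        return self.geometry / BOHR_TO_ANGSTROM

    @property
    def masses_me(self) -> np.ndarray:
        """Masses in electron-mass units (atomic units)."""
        return self.masses * AMU_TO_ME


@dataclass
class Spectrum:
    """Broadened intensity on a strictly increasing wavenumber grid (cm^-1)."""

    grid: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.size == 0:
            raise ValidationError("spectrum grid must be a nonempty 1-D array")
        if self.grid.shape != self.values.shape:
            raise ValidationError("grid and values must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("spectrum grid must be strictly increasing")
        if np.any(self.values < 0):
            raise ValidationError("spectrum values must be nonnegative")

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid.copy(), self.values.copy(), dict(self.meta))


@dataclass
class TransitionRecord:
    """One ensemble member's vertical excitation (cm^-1) and oscillator strength."""

    excitation_energy: float
    oscillator_strength: float
    source_index: int = -1

    def __post_init__(self) -> None:
        self.excitation_energy = float(self.excitation_energy)
        self.oscillator_strength = float(self.oscillator_strength)
        if not np.isfinite(self.excitation_energy):
            raise ValidationError("excitation_energy must be finite")
        if self.oscillator_strength < 0:
            raise ValidationError("oscillator_strength must be nonnegative")


# ---------------------------------------------------------------------------
# State-bundle I/O (structured JSON text; schema keys carry their units)
# ---------------------------------------------------------------------------

_OPTIONAL_KEYS = {
    "hessian_hartree_bohr2": "hessian",
    "gradient_hartree_bohr": "gradient",
    "transition_dipole_au": "transition_dipole",
    "oscillator_strength": "oscillator_strength",
}


def write_bundle(bundle: ElectronicStateBundle, path) -> None:
    doc: dict = {
        "label": bundle.label,
        "elements": bundle.elements,
        "geometry_angstrom": bundle.geometry.tolist(),
        "masses_amu": bundle.masses.tolist(),
        "energy_hartree": bundle.energy,
    }
    if bundle.hessian is not None:
        doc["hessian_hartree_bohr2"] = bundle.hessian.tolist()
    if bundle.gradient is not None:
        doc["gradient_hartree_bohr"] = bundle.gradient.tolist()
    if bundle.transition_dipole is not None:
        doc["transition_dipole_au"] = bundle.transition_dipole.tolist()
    if bundle.oscillator_strength is not None:
        doc["oscillator_strength"] = bundle.oscillator_strength
    Path(path).write_text(json.dumps(doc, indent=1))


def read_bundle(path) -> ElectronicStateBundle:
    """Read and validate a state bundle from its structured-text schema."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid structured text ({exc})") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    kwargs = {}
    for key, dest in (("label", "label"), ("elements", "elements"),
                      ("geometry_angstrom", "geometry"), ("masses_amu", "masses"),
                      ("energy_hartree", "energy")):
        if key not in doc:
            raise ParseError(f"{path}: missing required field {key!r}")
        kwargs[dest] = doc[key]
    for key, dest in _OPTIONAL_KEYS.items():
        if key in doc:
            kwargs[dest] = doc[key]
    unknown = set(doc) - {"label", "elements", "geometry_angstrom", "masses_amu",
                          "energy_hartree", *_OPTIONAL_KEYS}
    if unknown:
        raise ParseError(f"{path}: unknown field(s) {sorted(unknown)}")
    try:
        return ElectronicStateBundle(**kwargs)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Spectrum I/O: two-column CSV with '#'-prefixed metadata lines
# ---------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path) -> None:
    lines = []
    for key in sorted(spectrum.meta):
        lines.append(f"# {key}: {spectrum.meta[key]}")
    lines.append("wavenumber_cm1,epsilon")
    for x, y in zip(spectrum.grid, spectrum.values):
        lines.append(f"{float(x)!r},{float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> Spectrum:
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    header_seen = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = _parse_meta_value(val.strip())
            continue
        if not header_seen:
            if line != "wavenumber_cm1,epsilon":
                raise ParseError(f"{path}: expected header 'wavenumber_cm1,epsilon'")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}: malformed data row {line!r}")
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    if not header_seen:
        raise ParseError(f"{path}: missing header line")
    return Spectrum(np.array(xs), np.array(ys), meta)


def _parse_meta_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


# ---------------------------------------------------------------------------
# XYZ geometries (Angstrom)
# ---------------------------------------------------------------------------

def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Read a single-frame XYZ file; returns (elements, natoms x 3 Angstrom)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: first line must be the atom count") from exc
    if len(lines) < n + 2:
        raise ParseError(f"{path}: expected {n} coordinate lines")
    elements, coords = [], []
    for raw in lines[2:2 + n]:
        parts = raw.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: malformed coordinate line {raw!r}")
        elements.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    return elements, np.array(coords)


def write_xyz(elements: Sequence[str], geometry: np.ndarray, path, comment: str = "") -> None:
    geometry = np.asarray(geometry, dtype=float)
    lines = [str(len(elements)), comment]
    for el, (x, y, z) in zip(elements, geometry):
        lines.append(f"{el} {x: .10f} {y: .10f} {z: .10f}")
    Path(path).write_text("\n".join(lines) + "\n")
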