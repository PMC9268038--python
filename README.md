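# vibronic

A toolkit for simulating the absorption spectra of chromophores with strong
vibronic structure under harmonic models, built around four pieces:

* **Franck–Condon engines** — exact multidimensional harmonic-oscillator
  overlaps under a Duschinsky rotation + displacement, via a stable
  generating-function recursion. A time-independent (TI) engine enumerates
  assigned stick spectra at 0 K and finite temperature with class-based
  prescreening; a time-dependent (TD) engine evaluates the closed-form
  thermal dipole-correlation function and Fourier-transforms it, at a cost
  independent of temperature.
* **Harmonic surface models** — the final-state surface can be built as
  adiabatic Hessian (AH), adiabatic shift (AS), vertical Hessian (VH) or
  vertical gradient (VG) from per-state "bundle" files (geometry, masses,
  Hessian, gradient, energies, transition dipole).
* **Nuclear-ensemble spectra** — Wigner (quantum, any temperature including
  0 K zero-point) and classical-Boltzmann harmonic sampling of ground-state
  geometries, vertical gaps on the analytic final surface, Gaussian
  convolution, and convergence-vs-ensemble-size analysis. External
  excitation tables can be injected as a records CSV.
* **Spectrum tools and a force-field audit** — stick convolution with both
  sigma and HWHM broadening conventions, peak finding, band spacings,
  lambda_max, rigid shifting, spectral distances; plus a bond-length
  alternation (BLA) audit of conjugated-chain force-field parameters
  against QM reference bond lengths (reference table packaged).

A model-system generator (`vibronic.model_systems`) builds analytic
displaced/rotated harmonic chromophores — including a six-mode cyanine-like
fixture on published excited-state frequencies (34.9, 354, 1136, 1378,
1415, 1525 cm^-1) — so every engine is exercised without any
quantum-chemistry run.

## CLI

```bash
# analytic fixtures
vibronic model-system --kind cy3like --huang-rhys 0.8,0.05,0.12,0.1,0.1,0.14 --out cy3.json
vibronic model-system --kind random --natoms 4 --seed 1 --out bundle.json

# Franck-Condon spectrum from a pair of state bundles
vibronic fc --initial ground.json --final excited.json --model AH \
    --scheme TD --temperature 298 --hwhm 150 --grid 10000:30000:1 --out fc.csv

# nuclear-ensemble spectrum on an analytic map
vibronic ensemble --map cy3.json --method wigner --n 200 --seed 42 --out wigner.csv

# post-processing and the force-field audit
vibronic spectrum-tools peaks fc.csv
vibronic spectrum-tools shift fc.csv --mode match_max --reference 18194 --out shifted.csv
vibronic bla --table
vibronic modes --bundle bundle.json --out modes.tsv
```

State bundles are JSON with unit-bearing keys (`geometry_angstrom`,
`masses_amu`, `energy_hartree`, `hessian_hartree_bohr2`,
`gradient_hartree_bohr`, `transition_dipole_au`, `oscillator_strength`);
spectra are two-column CSV (`wavenumber_cm1,epsilon`) with `#` metadata
lines. Internals run in atomic units with fixed constants
(1 hartree = 219474.6313632 cm^-1, kB = 0.695034800 cm^-1/K,
1 amu = 1822.888486 m_e).

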