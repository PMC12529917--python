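"""Unit conversions used across the pipeline.

Every physical conversion in the package funnels through this module so
that the constants are auditable in one place.  CODATA values come from
:mod:`scipy.constants`.

Conventions
-----------
* Vibrational frequencies are stored as wavenumbers in cm^-1; angular
  frequencies (rad/s) are derived as ``omega = 2*pi*c*nu_tilde``.
* Laser frequencies are angular, quoted in THz (1 THz = 1e12 rad/s), so
  a 532 nm laser corresponds to 2*pi*c/532 nm = 3540.70 THz.
* Energies are kJ/mol; pressure-volume work converts MPa * Angstrom^3
  per cell into kJ/mol per cell.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _const

#: Speed of light in vacuum, m/s.
C_LIGHT = _const.c
#: Planck constant over 2*pi, J*s.
HBAR = _const.hbar
#: Boltzmann constant, J/K.
K_B = _const.k
#: Avogadro constant, 1/mol.
N_A = _const.N_A

#: kJ/mol per (MPa * Angstrom^3) of pressure-volume work per cell.
KJMOL_PER_MPA_A3 = 1e6 * 1e-30 * N_A / 1e3


def wavenumber_to_angular(freq_cm1):
    """Angular frequency (rad/s) for a wavenumber in cm^-1."""
    return 2.0 * np.pi * C_LIGHT * np.asarray(freq_cm1) * 100.0


def wavelength_nm_to_angular_thz(wavelength_nm: float) -> float:
    """Angular frequency in THz of light with the given vacuum wavelength.

    532 nm -> 3540.70 THz, the convention used for the incoming-laser
    correction of polycrystalline Raman intensities.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 2.0 * np.pi * C_LIGHT / (wavelength_nm * 1e-9) / 1e12


def photon_energy_over_kt(freq_cm1, temperature_k):
    """Dimensionless ratio hbar*omega / k_B*T for a wavenumber in cm^-1."""
    return HBAR * wavenumber_to_angular(freq_cm1) / (K_B * temperature_k)
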