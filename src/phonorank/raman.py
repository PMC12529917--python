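"""Polycrystalline Raman spectrum synthesis with laser/temperature correction.

The observable intensity of a Raman-active mode m depends on the incoming
laser and the thermal population of the mode.  With omega_0 the angular
frequency of the laser and omega_m that of the mode,

    I_m = (omega_0 - omega_m)^4 / (c^4 hbar omega_m)
          * [ 1/(exp(hbar omega_m / k_B T) - 1) + 1 ] * I'_m

where I'_m is the orientation-averaged scattering activity of the mode's
polarizability-derivative tensor.  At T = 0 the occupation bracket is
exactly 1.  The absolute scale is irrelevant here: spectra are normalized
to their highest peak, matching the usual presentation of low-frequency
polymorph spectra.

Powder (unpolarized backscattering) averaging uses the standard rotational
invariants of a symmetric tensor a:

    abar   = (a_xx + a_yy + a_zz) / 3
    gamma2 = 1/2 [ (a_xx-a_yy)^2 + (a_yy-a_zz)^2 + (a_zz-a_xx)^2 ]
             + 3 (a_xy^2 + a_yz^2 + a_zx^2)
    activity = 45 abar^2 + 7 gamma2

Lines are broadened with unit-area Lorentzians of fixed FWHM (default
10 cm^-1, mimicking finite experimental resolution) and summed on a regular
wavenumber grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from . import units
from .mode_data import ModeSet

__all__ = [
    "SpectrumTrace",
    "DEFAULT_LASER_WAVELENGTH_NM",
    "DEFAULT_FWHM_CM1",
    "correction_factor",
    "powder_activity",
    "lorentzian",
    "synthesize_spectrum",
]

logger = logging.getLogger(__name__)

DEFAULT_LASER_WAVELENGTH_NM = 532.0
DEFAULT_FWHM_CM1 = 10.0
DEFAULT_TEMPERATURE_K = 300.0


@dataclass
class SpectrumTrace:
    """A broadened Raman spectrum on a strictly increasing wavenumber grid."""

    grid: np.ndarray          # cm^-1
    intensity: np.ndarray     # nonnegative, same length as grid
    normalization: str        # "none" | "max-peak"
    temperature: float        # K
    laser_omega0: float       # angular frequency, THz

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.shape != self.intensity.shape:
            raise ValueError("grid and intensity must have the same length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.intensity < -1e-300):
            raise ValueError("intensities must be nonnegative")

    def measured_fwhm(self) -> float:
        """Width of the highest peak at half its maximum, by linear
        interpolation of the half-maximum crossings on either side."""
        y = self.intensity
        k = int(np.argmax(y))
        half = y[k] / 2.0
        x = self.grid
        # walk left
        i = k
        while i > 0 and y[i] > half:
            i -= 1
        left = np.interp(half, [y[i], y[i + 1]], [x[i], x[i + 1]]) if i < k else x[k]
        j = k
        while j < y.size - 1 and y[j] > half:
            j += 1
        right = (
            np.interp(half, [y[j], y[j - 1]], [x[j], x[j - 1]]) if j > k else x[k]
        )
        return float(right - left)


def correction_factor(
    freq_m: float,
    omega0_thz: float = units.wavelength_nm_to_angular_thz(DEFAULT_LASER_WAVELENGTH_NM),
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Laser/temperature correction of a Raman line at ``freq_m`` cm^-1.

    Returns ``(omega0 - omega_m)^4 / (c^4 hbar omega_m) * [n_B + 1]`` with
    ``n_B`` the Bose occupation; both frequencies are treated as angular.
    The scale carries the (arbitrary) units of the activity; only ratios
    between lines matter after max-normalization.

    Raises for nonpositive ``freq_m``: acoustic and imaginary modes carry no
    Raman line, and the Bose factor diverges as the frequency approaches 0.
    """
    if freq_m <= 0:
        raise ValueError(f"correction_factor needs freq > 0, got {freq_m}")
    if temperature < 0:
        raise ValueError("temperature must be nonnegative")
    omega_m = units.wavenumber_to_angular(freq_m)          # rad/s
    omega0 = omega0_thz * 1e12                             # rad/s
    prefactor = (omega0 - omega_m) ** 4 / (
        units.C_LIGHT**4 * units.HBAR * omega_m
    )
    if temperature == 0:
        bracket = 1.0
    else:
        x = float(units.photon_energy_over_kt(freq_m, temperature))
        # beyond x ~ 700 the occupation underflows double precision entirely
        bracket = 1.0 / np.expm1(x) + 1.0 if x < 700.0 else 1.0
    return float(prefactor * bracket)


def powder_activity(tensor: np.ndarray, sym_tol: float = 1e-8) -> float:
    """Rotation-invariant powder scattering activity 45*abar^2 + 7*gamma2."""
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError(f"expected a 3x3 tensor, got shape {t.shape}")
    scale = max(1.0, float(np.max(np.abs(t))))
    if np.max(np.abs(t - t.T)) > sym_tol * scale:
        raise ValueError("Raman tensor must be symmetric")
    abar = np.trace(t) / 3.0
    gamma2 = 0.5 * (
        (t[0, 0] - t[1, 1]) ** 2
        + (t[1, 1] - t[2, 2]) ** 2
        + (t[2, 2] - t[0, 0]) ** 2
    ) + 3.0 * (t[0, 1] ** 2 + t[1, 2] ** 2 + t[2, 0] ** 2)
    return float(45.0 * abar**2 + 7.0 * gamma2)


def lorentzian(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzian line shape of the given FWHM."""
    half = fwhm / 2.0
    return (half / np.pi) / ((grid - center) ** 2 + half**2)


def synthesize_spectrum(
    ms: ModeSet,
    temperature: float = DEFAULT_TEMPERATURE_K,
    laser_wavelength: float = DEFAULT_LASER_WAVELENGTH_NM,
    fwhm: float = DEFAULT_FWHM_CM1,
    freq_range: Tuple[float, float] = (0.0, 250.0),
    grid_step: float = 0.5,
    normalize: bool = True,
) -> SpectrumTrace:
    """Synthesize the polycrystalline Raman spectrum of a mode set.

    Every Raman-active nontranslational Gamma mode with positive frequency
    contributes a Lorentzian line of area ``powder_activity * correction``;
    modes outside ``freq_range`` still contribute their tails.  Imaginary
    and translational modes are skipped with a logged count (only real
    optical modes are plotted); modes without a Raman tensor are treated
    as Raman-inactive.  The summed trace is normalized to its highest peak
    unless ``normalize`` is false.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    lo, hi = freq_range
    if not lo < hi:
        raise ValueError("freq_range must satisfy lo < hi")
    omega0 = units.wavelength_nm_to_angular_thz(laser_wavelength)

    gamma_modes = ms.gamma_modes(include_translations=True)
    active = []
    n_skipped_trans = n_skipped_imag = n_inactive = 0
    for m in gamma_modes:
        if m.is_translation:
            n_skipped_trans += 1
        elif m.frequency <= 0:
            n_skipped_imag += 1
        elif m.raman_tensor is None:
            n_inactive += 1
        else:
            active.append(m)
    if n_skipped_trans or n_skipped_imag:
        logger.info(
            "skipped %d translational and %d imaginary/zero modes",
            n_skipped_trans,
            n_skipped_imag,
        )
    if not active:
        raise ValueError("mode set carries no Raman tensors at Gamma")

    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    intensity = np.zeros_like(grid)
    for m in active:
        line = powder_activity(m.raman_tensor) * correction_factor(
            m.frequency, omega0, temperature
        )
        intensity += line * lorentzian(grid, m.frequency, fwhm)

    norm = "none"
    if normalize:
        peak = intensity.max()
        if peak > 0:
            intensity = intensity / peak
        norm = "max-peak"
    return SpectrumTrace(
        grid=grid,
        intensity=intensity,
        normalization=norm,
        temperature=temperature,
        laser_omega0=omega0,
    )
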