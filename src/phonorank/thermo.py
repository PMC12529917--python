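"""Harmonic Gibbs free energy with frequency scaling and band partitioning.

Under the harmonic approximation at fixed (athermal) volume, the Gibbs free
energy of a crystal is

    F(T, p) = E_DFT + sum_{i,q} w_q [ hbar*omega_iq / 2
              + k_B T ln(1 - exp(-hbar*omega_iq / k_B T)) ] + p V

with the q-point weights w_q summing to 1 over the Brillouin-zone sample.
Energies are handled in kJ/mol per cell internally and reported per formula
unit.  Because the volume is fixed per polymorph, F is affine in p, a fact
the phase-diagram stage exploits.

Empirical frequency scaling corrects systematic harmonic/DFT errors of
intramolecular modes: a method-dependent factor multiplies all frequencies
strictly above a threshold (default 250 cm^-1), leaving the intermolecular
lattice modes untouched, and is applied before any thermodynamic evaluation
so both zero-point and thermal terms see scaled frequencies.  A registry of
published factors for common method/basis combinations ships as
:data:`SCALING_FACTOR_REGISTRY`.

The free-energy difference between two polymorphs can be partitioned by
spectral band — static (electronic + pV), lattice modes below 250 cm^-1,
fingerprint modes 250-1750 cm^-1, an expected-empty gap band 1750-2500
cm^-1, and X-H stretches above 2500 cm^-1 — with the parts summing exactly
to the total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import units
from .mode_data import ModeSet, validate_for_thermo
from .synthetic_data import replace_mode

__all__ = [
    "ScalingScheme",
    "SCALING_FACTOR_REGISTRY",
    "FreeEnergySurface",
    "BandPartition",
    "DEFAULT_PARTITION_BANDS",
    "apply_scaling",
    "mode_free_energy",
    "gibbs_free_energy",
    "partition_delta_f",
    "scheme_for_method",
]

logger = logging.getLogger(__name__)

#: Published uniform frequency scaling factors, keyed by "Hamiltonian/basis".
#: The plane-wave PBE entry is 1.0 (no scaling); the pob-TZVP/PBE entry
#: reuses the def2-TZVP/PBE value, the closest benchmarked combination.
SCALING_FACTOR_REGISTRY: Dict[str, float] = {
    "PBE0/6-31G**": 0.9509,
    "PBE0/def2-SVP": 0.9555,
    "PBE0/pob-TZVP": 0.9594,
    "PBE0/def2-TZVP": 0.9591,
    "PBE/6-31G**": 0.9848,
    "PBE/def2-SVP": 0.9904,
    "PBE/pob-TZVP": 0.9923,
    "PBE/def2-TZVP": 0.9923,
    "PAW/PBE": 1.0,
}

DEFAULT_SCALING_THRESHOLD = 250.0  # cm^-1


@dataclass(frozen=True)
class ScalingScheme:
    """Uniform scaling of frequencies strictly above a threshold."""

    factor: float = 1.0
    threshold: float = DEFAULT_SCALING_THRESHOLD
    method_tag: str = ""

    def __post_init__(self):
        if not self.factor > 0:
            raise ValueError("scaling factor must be positive")


IDENTITY_SCALING = ScalingScheme(1.0, DEFAULT_SCALING_THRESHOLD, "unscaled")


def scheme_for_method(method_tag: str, threshold: float = DEFAULT_SCALING_THRESHOLD) -> ScalingScheme:
    """Look up the shipped scaling factor for a method tag."""
    try:
        factor = SCALING_FACTOR_REGISTRY[method_tag]
    except KeyError:
        raise KeyError(
            f"no scaling factor registered for {method_tag!r}; "
            f"known tags: {sorted(SCALING_FACTOR_REGISTRY)}"
        ) from None
    return ScalingScheme(factor=factor, threshold=threshold, method_tag=method_tag)


def apply_scaling(ms: ModeSet, scheme: ScalingScheme) -> ModeSet:
    """Return a copy with frequencies strictly above the threshold scaled.

    Eigenvectors, tensors and all metadata are untouched; frequencies at or
    below the threshold pass through unchanged.
    """
    new_modes = []
    for m in ms.modes:
        m2 = replace_mode(m)
        if m2.frequency > scheme.threshold:
            m2.frequency = m2.frequency * scheme.factor
        new_modes.append(m2)
    return ModeSet(
        cell=ms.cell,
        n_atoms=ms.n_atoms,
        symbols=list(ms.symbols),
        masses=ms.masses.copy(),
        qpoints=list(ms.qpoints),
        modes=new_modes,
    )


def mode_free_energy(freq: float, temperature: float) -> float:
    """Harmonic free energy of one mode, kJ per mole of cells.

    ``hbar*omega/2 + k_B T ln(1 - exp(-hbar*omega/k_B T))`` for a wavenumber
    ``freq`` in cm^-1.  At T = 0 this is exactly the zero-point term.
    """
    zp, th = _mode_free_energy_terms(freq, temperature)
    return zp + th


def _mode_free_energy_terms(freq: float, temperature: float) -> Tuple[float, float]:
    """(zero-point, thermal) parts, kJ per mole of cells."""
    if freq <= 0:
        raise ValueError(f"mode free energy needs freq > 0, got {freq}")
    if temperature < 0:
        raise ValueError("temperature must be nonnegative")
    hbar_omega = units.HBAR * units.wavenumber_to_angular(freq)  # J
    zp = units.N_A * hbar_omega / 2.0 / 1e3
    if temperature == 0:
        return zp, 0.0
    x = hbar_omega / (units.K_B * temperature)
    thermal = units.N_A * units.K_B * temperature * np.log(-np.expm1(-x)) / 1e3
    return zp, float(thermal)


@dataclass
class FreeEnergySurface:
    """F(T, p) of one polymorph, kJ/mol per formula unit.

    ``f`` has shape (len(temperatures), len(pressures)) and decomposes as
    ``electronic + zero_point + thermal + pv`` at every node; ``electronic``
    and ``zero_point`` are scalars broadcast over the grid, ``thermal``
    varies with T and ``pv`` with p.
    """

    polymorph: str
    temperatures: np.ndarray      # K
    pressures: np.ndarray         # MPa
    f: np.ndarray                 # (nT, nP)
    electronic: float             # per formula
    zero_point: float             # per formula
    thermal: np.ndarray           # (nT,), per formula
    pv: np.ndarray                # (nP,), per formula
    volume_per_formula: float     # Angstrom^3

    def at(self, temperature: float, pressure: float) -> float:
        """F at one node (must lie on the grid)."""
        it = _grid_index(self.temperatures, temperature, "temperature")
        ip = _grid_index(self.pressures, pressure, "pressure")
        return float(self.f[it, ip])


def _grid_index(grid: np.ndarray, value: float, what: str) -> int:
    idx = np.flatnonzero(np.isclose(grid, value, rtol=0, atol=1e-9))
    if idx.size != 1:
        raise ValueError(f"{what} {value} is not a node of the grid")
    return int(idx[0])


def gibbs_free_energy(
    ms: ModeSet,
    temperatures: Sequence[float],
    pressure: float = 0.0,
    scheme: ScalingScheme = IDENTITY_SCALING,
    pressures: Optional[Sequence[float]] = None,
) -> FreeEnergySurface:
    """Harmonic Gibbs free energy per formula unit on a temperature grid.

    The scaling scheme is applied first; the weighted mode sum runs over all
    nontranslational modes of every q-point; the pV term uses the fixed
    optimized cell volume.  Refuses mode sets with imaginary nontranslational
    modes, listing them.
    """
    report = validate_for_thermo(ms)
    if report.imaginary:
        raise ValueError(
            f"mode set {ms.cell.label!r} is not thermo-ready: imaginary "
            f"nontranslational modes at indices {report.imaginary}"
        )
    if report.weight_sum_deviation > 1e-10:
        raise ValueError(
            f"q-point weights sum deviates by {report.weight_sum_deviation:.2e}"
        )

    scaled = apply_scaling(ms, scheme)
    t_grid = np.asarray(temperatures, dtype=float)
    p_grid = (
        np.asarray(pressures, dtype=float)
        if pressures is not None
        else np.array([pressure], dtype=float)
    )

    z = ms.cell.z_formula
    electronic = ms.cell.e_electronic / z
    vol_per_formula = ms.cell.volume / z
    pv = p_grid * ms.cell.volume * units.KJMOL_PER_MPA_A3 / z

    weight_of = {q.index: q.weight for q in scaled.qpoints}
    zero_point = 0.0
    thermal = np.zeros_like(t_grid)
    skipped = set(report.classified_translational)
    for k, m in enumerate(scaled.modes):
        if m.is_translation or k in skipped:
            continue
        w = weight_of[m.qpoint_index]
        zp, _ = _mode_free_energy_terms(m.frequency, 0.0)
        zero_point += w * zp / z
        for it, t in enumerate(t_grid):
            _, th = _mode_free_energy_terms(m.frequency, float(t))
            thermal[it] += w * th / z

    f = electronic + zero_point + thermal[:, None] + pv[None, :]
    return FreeEnergySurface(
        polymorph=ms.cell.label,
        temperatures=t_grid,
        pressures=p_grid,
        f=f,
        electronic=electronic,
        zero_point=zero_point,
        thermal=thermal,
        pv=pv,
        volume_per_formula=vol_per_formula,
    )


#: Spectral bands of the free-energy partition, [lo, hi) in cm^-1.  The
#: 1750-2500 cm^-1 gap band is expected empty for acetaminophen-like spectra
#: and exists so the bands exactly partition [0, inf).
DEFAULT_PARTITION_BANDS: Tuple[Tuple[str, float, float], ...] = (
    ("low", 0.0, 250.0),
    ("medium", 250.0, 1750.0),
    ("gap", 1750.0, 2500.0),
    ("high", 2500.0, float("inf")),
)


@dataclass
class BandPartition:
    """Band-resolved decomposition of a polymorph free-energy difference.

    ``delta_f_dft`` is the static part (electronic energy difference with
    the pV difference folded in; at p = 0 the fold is zero).  The parts sum
    exactly to ``delta_f_total``.
    """

    bands: Tuple[Tuple[str, float, float], ...]
    delta_f_per_band: Dict[str, float]
    delta_f_dft: float
    delta_f_total: float
    temperature: float
    pressure: float

    @property
    def residual(self) -> float:
        return self.delta_f_total - self.delta_f_dft - sum(
            self.delta_f_per_band.values()
        )


def _check_bands(bands) -> None:
    prev_hi = 0.0
    for name, lo, hi in bands:
        if not lo < hi:
            raise ValueError(f"band {name}: need lo < hi")
        if abs(lo - prev_hi) > 1e-12:
            raise ValueError(
                f"bands must partition [0, inf) without gaps or overlaps; "
                f"band {name} starts at {lo}, previous ends at {prev_hi}"
            )
        prev_hi = hi
    if not np.isinf(prev_hi):
        raise ValueError("last band must extend to infinity")


def _band_vibrational_f(
    ms: ModeSet, scheme: ScalingScheme, bands, temperature: float
) -> Dict[str, float]:
    """Per-band vibrational free energy, kJ/mol per formula.

    Band membership is decided on the scaled frequency (the frequency that
    actually enters the mode sum).
    """
    scaled = apply_scaling(ms, scheme)
    report = validate_for_thermo(scaled)
    weight_of = {q.index: q.weight for q in scaled.qpoints}
    z = ms.cell.z_formula
    out = {name: 0.0 for name, _, _ in bands}
    skipped = set(report.classified_translational)
    for k, m in enumerate(scaled.modes):
        if m.is_translation or k in skipped:
            continue
        contrib = weight_of[m.qpoint_index] * mode_free_energy(
            m.frequency, temperature
        ) / z
        for name, lo, hi in bands:
            if lo <= m.frequency < hi:
                out[name] += contrib
                break
    return out


def partition_delta_f(
    a: FreeEnergySurface,
    b: FreeEnergySurface,
    ms_a: ModeSet,
    ms_b: ModeSet,
    bands: Tuple[Tuple[str, float, float], ...] = DEFAULT_PARTITION_BANDS,
    temperature: float = 298.0,
    pressure: float = 0.0,
    scheme_a: ScalingScheme = IDENTITY_SCALING,
    scheme_b: ScalingScheme = IDENTITY_SCALING,
) -> BandPartition:
    """Decompose Delta F = F_a - F_b by spectral band at one (T, p) node.

    The schemes must be the ones used to build the surfaces, so that the
    static part plus the band sums reproduce the total exactly.  A warning
    is issued when the gap band carries weight (unexpected for
    acetaminophen-like spectra).
    """
    _check_bands(bands)
    total = a.at(temperature, pressure) - b.at(temperature, pressure)
    static = (a.electronic - b.electronic) + (
        pressure
        * (a.volume_per_formula - b.volume_per_formula)
        * units.KJMOL_PER_MPA_A3
    )
    fa = _band_vibrational_f(ms_a, scheme_a, bands, temperature)
    fb = _band_vibrational_f(ms_b, scheme_b, bands, temperature)
    per_band = {name: fa[name] - fb[name] for name, _, _ in bands}
    if abs(per_band.get("gap", 0.0)) > 1e-12:
        warnings.warn(
            "the 1750-2500 cm^-1 gap band carries nonzero free-energy weight",
            stacklevel=2,
        )
    return BandPartition(
        bands=tuple(bands),
        delta_f_per_band=per_band,
        delta_f_dft=static,
        delta_f_total=total,
        temperature=temperature,
        pressure=pressure,
    )
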