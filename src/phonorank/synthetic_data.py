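"""Synthetic two-polymorph phonon data with a "method change" perturbation.

Real input to this pipeline is cluster-scale DFT lattice-dynamics output.
This module generates mode sets with the same statistical structure so every
downstream stage (Raman synthesis, mode matching, free-energy ranking,
phase diagrams) is exercisable and testable at desk scale:

* frequencies grouped into the three spectral regions of an acetaminophen-like
  molecular crystal — a lattice (intermolecular) band below 250 cm^-1, an
  intramolecular fingerprint band 250-1750 cm^-1 and X-H stretches above
  2800 cm^-1, with the 1750-2500 cm^-1 window empty;
* orthonormal mass-weighted eigenvectors, with the three rigid translations
  pinned at the Gamma point;
* random symmetric Raman tensors whose magnitude decays with band frequency
  (lattice modes dominate the low-frequency powder spectrum);
* a :func:`perturb_method` operator mimicking a basis-set/Hamiltonian switch:
  within-block mode shuffling, multiplicative frequency bias plus relative
  Gaussian noise, pairwise eigenvector mixing among near-degenerate modes,
  and an electronic-energy shift — returning the ground-truth permutation so
  assignment recovery can be scored exactly.

Everything is driven by ``numpy.random.default_rng`` seeds; a fixed seed
fixes every downstream number in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .mode_data import (
    CrystalCell,
    ModeSet,
    PhononMode,
    QPoint,
    translation_basis,
)

__all__ = [
    "BandSpec",
    "PerturbationSpec",
    "DEFAULT_BANDS",
    "generate_polymorph_pair",
    "generate_modeset",
    "perturb_method",
]

# acetaminophen formula unit C8H9NO2, cycled to fill the cell
_FORMULA_SYMBOLS = ["C"] * 8 + ["H"] * 9 + ["N"] + ["O"] * 2
_MASSES_AMU = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


@dataclass(frozen=True)
class BandSpec:
    """One spectral region: its frequency window and share of the modes."""

    name: str                      # lattice | fingerprint | stretch
    frequency_range: Tuple[float, float]   # [lo, hi] cm^-1
    mode_fraction: float           # fraction of nontranslational modes

    def __post_init__(self):
        lo, hi = self.frequency_range
        if not lo < hi:
            raise ValueError(f"band {self.name}: need lo < hi, got [{lo}, {hi}]")
        if not 0 <= self.mode_fraction <= 1:
            raise ValueError(f"band {self.name}: fraction must lie in [0, 1]")


#: Spectral regions of an acetaminophen-like crystal: ~15% lattice modes,
#: ~70% fingerprint, ~15% X-H stretches; 1750-2500 cm^-1 left empty.
DEFAULT_BANDS = (
    BandSpec("lattice", (20.0, 250.0), 0.15),
    BandSpec("fingerprint", (250.0, 1750.0), 0.70),
    BandSpec("stretch", (2800.0, 3600.0), 0.15),
)

#: Raman-tensor magnitude per band; lattice modes dominate the low-frequency
#: powder spectrum, stretches are comparatively weak.
_RAMAN_SCALE = {"lattice": 1.0, "fingerprint": 0.5, "stretch": 0.3}


@dataclass(frozen=True)
class PerturbationSpec:
    """Parameters of the method-change perturbation.

    ``freq_scale`` is a multiplicative bias on all frequencies,
    ``freq_noise_sd`` a relative Gaussian standard deviation,
    ``mixing_angle_deg`` the rotation applied pairwise within clusters of
    near-degenerate eigenvectors, and ``energy_shift`` (kJ/mol per formula)
    is added to the electronic energy.
    """

    freq_scale: float = 1.0
    freq_noise_sd: float = 0.0
    mixing_angle_deg: float = 0.0
    energy_shift: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.freq_noise_sd < 0:
            raise ValueError("freq_noise_sd must be nonnegative")
        if not 0 <= self.mixing_angle_deg <= 90:
            raise ValueError("mixing_angle_deg must lie in [0, 90]")


def _fix_signs(columns: np.ndarray) -> np.ndarray:
    """Make the first nonzero component of each column positive (in place)."""
    for j in range(columns.shape[1]):
        col = columns[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            columns[:, j] = -col
    return columns


def _random_orthonormal_completion(
    fixed: Optional[np.ndarray], dim: int, n_new: int, rng: np.random.Generator
) -> np.ndarray:
    """n_new orthonormal columns orthogonal to the fixed ones, seed-stable.

    A seeded Gaussian matrix is orthogonalized by QR; signs are fixed so the
    output is reproducible across platforms.
    """
    gauss = rng.standard_normal((dim, n_new))
    if fixed is not None and fixed.size:
        stacked = np.hstack([fixed, gauss])
        q, r = np.linalg.qr(stacked)
        q = q * np.sign(np.diag(r))
        new = q[:, fixed.shape[1] :]
    else:
        q, r = np.linalg.qr(gauss)
        new = q * np.sign(np.diag(r))
    return _fix_signs(new.copy())


def _band_counts(bands: Sequence[BandSpec], n_modes: int) -> List[int]:
    fractions = np.array([b.mode_fraction for b in bands], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"band fractions sum to {fractions.sum()}, expected 1")
    counts = np.floor(fractions * n_modes).astype(int)
    # distribute the remainder to the largest fractional parts
    remainder = n_modes - counts.sum()
    order = np.argsort(-(fractions * n_modes - counts))
    for i in range(remainder):
        counts[order[i % len(bands)]] += 1
    return counts.tolist()


def _random_symmetric(rng: np.random.Generator, scale: float) -> np.ndarray:
    g = rng.standard_normal((3, 3)) * scale
    return (g + g.T) / 2.0


def generate_modeset(
    n_atoms: int,
    label: str,
    z_formula: int,
    volume: float,
    e_electronic_per_formula: float,
    bands: Sequence[BandSpec],
    n_qpoints: int,
    seed: int,
    method: str = "synthetic",
    irreps: Optional[Sequence[str]] = None,
) -> ModeSet:
    """Generate one valid ModeSet with the configured band structure.

    Frequencies are uniform within each band and sorted ascending at every
    q-point.  At Gamma the first three modes are the exact mass-weighted
    rigid translations at near-zero frequency; the remaining eigenvectors
    are a random orthonormal completion.  Raman tensors are attached to the
    Gamma modes only (the Raman-probed q-point).  When ``irreps`` is given,
    labels are assigned cyclically to the nontranslational modes.
    """
    if n_atoms < 2:
        raise ValueError("n_atoms must be at least 2")
    rng = np.random.default_rng(seed)

    symbols = [_FORMULA_SYMBOLS[i % len(_FORMULA_SYMBOLS)] for i in range(n_atoms)]
    masses = np.array([_MASSES_AMU[s] for s in symbols])

    cell = CrystalCell(
        label=label,
        volume=volume,
        z_formula=z_formula,
        e_electronic=e_electronic_per_formula * z_formula,
        method=method,
    )

    weight = 1.0 / n_qpoints
    qpoints = [QPoint(index=0, coordinates=(0.0, 0.0, 0.0), weight=weight)]
    for i in range(1, n_qpoints):
        coords = tuple(rng.uniform(-0.5, 0.5, size=3).round(6))
        qpoints.append(QPoint(index=i, coordinates=coords, weight=weight))

    n_modes = 3 * n_atoms
    n_opt = n_modes - 3  # nontranslational ("optical") at Gamma
    modes: List[PhononMode] = []

    for q in qpoints:
        at_gamma = q.is_gamma
        n_band_modes = n_opt if at_gamma else n_modes
        counts = _band_counts(bands, n_band_modes)
        freqs = np.concatenate(
            [
                np.sort(rng.uniform(*b.frequency_range, size=c))
                for b, c in zip(bands, counts)
            ]
        )
        band_of = np.concatenate(
            [np.full(c, i, dtype=int) for i, c in enumerate(counts)]
        )
        order = np.argsort(freqs, kind="stable")
        freqs, band_of = freqs[order], band_of[order]

        if at_gamma:
            trans = translation_basis(masses)
            evecs = _random_orthonormal_completion(trans, n_modes, n_opt, rng)
            for k in range(3):
                modes.append(
                    PhononMode(
                        frequency=float(rng.uniform(0.0, 0.05)),
                        qpoint_index=q.index,
                        eigenvector=_fix_signs(trans[:, [k]].copy())[:, 0],
                        is_translation=True,
                    )
                )
        else:
            evecs = _random_orthonormal_completion(None, n_modes, n_modes, rng)

        for k in range(n_band_modes):
            band = bands[band_of[k]]
            tensor = (
                _random_symmetric(rng, _RAMAN_SCALE.get(band.name, 0.5))
                if at_gamma
                else None
            )
            irrep = irreps[k % len(irreps)] if irreps else None
            modes.append(
                PhononMode(
                    frequency=float(freqs[k]),
                    qpoint_index=q.index,
                    eigenvector=evecs[:, k],
                    irrep=irrep,
                    raman_tensor=tensor,
                )
            )

    return ModeSet(
        cell=cell,
        n_atoms=n_atoms,
        symbols=symbols,
        masses=masses,
        qpoints=qpoints,
        modes=modes,
    )


def generate_polymorph_pair(
    n_atoms: int,
    z_formulas: Tuple[int, int] = (4, 8),
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    delta_e_electronic: float = 1.0,
    n_qpoints: int = 1,
    seed: int = 0,
    volumes: Tuple[float, float] = (741.2, 1441.2),
    e_base_per_formula: float = -1.0e5,
    labels: Tuple[str, str] = ("form-I", "form-II"),
    irreps: Optional[Sequence[str]] = None,
) -> Tuple[ModeSet, ModeSet]:
    """Generate a two-polymorph pair sharing the same atoms.

    The defaults emulate the two common acetaminophen phases: formula-unit
    counts (4, 8) as in the monoclinic and orthorhombic cells, cell volumes
    at experimental scale, and per-formula electronic energies differing by
    exactly ``delta_e_electronic`` (kJ/mol per formula; positive means the
    second polymorph is electronically higher).
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2)
    ms_a = generate_modeset(
        n_atoms,
        label=labels[0],
        z_formula=z_formulas[0],
        volume=volumes[0],
        e_electronic_per_formula=e_base_per_formula,
        bands=bands,
        n_qpoints=n_qpoints,
        seed=int(seeds[0]),
        irreps=irreps,
    )
    ms_b = generate_modeset(
        n_atoms,
        label=labels[1],
        z_formula=z_formulas[1],
        volume=volumes[1],
        e_electronic_per_formula=e_base_per_formula + delta_e_electronic,
        bands=bands,
        n_qpoints=n_qpoints,
        seed=int(seeds[1]),
        irreps=irreps,
    )
    return ms_a, ms_b


def perturb_method(
    ms: ModeSet,
    spec: PerturbationSpec,
    cluster_gap: float = 5.0,
) -> Tuple[ModeSet, np.ndarray]:
    """Apply a method-change perturbation; return (perturbed set, truth).

    Within every (q-point, irrep) block of nontranslational modes:

    * eigenvectors of modes closer than ``cluster_gap`` cm^-1 are mixed
      pairwise by a rotation of exactly ``mixing_angle_deg`` degrees
      (successive pairs within each near-degenerate cluster);
    * frequencies are multiplied by ``freq_scale * (1 + eps)`` with
      ``eps ~ N(0, freq_noise_sd)``;
    * the modes are randomly shuffled within the block.

    The electronic energy is shifted by ``energy_shift * z_formula``
    (the shift is quoted per formula unit).  Translational modes are left
    in place and map to themselves.

    The returned ``truth`` array satisfies ``truth[j] = i``: the mode at
    position ``j`` of the perturbed set originates from mode ``i`` of the
    input (indices into ``ModeSet.modes``).
    """
    rng = np.random.default_rng(spec.seed)
    theta = np.deg2rad(spec.mixing_angle_deg)

    new_modes: List[Optional[PhononMode]] = [None] * len(ms.modes)
    truth = np.arange(len(ms.modes))

    # group global mode indices by (q, irrep), nontranslational only
    blocks: dict = {}
    for gi, m in enumerate(ms.modes):
        if m.is_translation:
            new_modes[gi] = replace_mode(m)
            continue
        blocks.setdefault((m.qpoint_index, m.irrep), []).append(gi)

    for key in sorted(blocks, key=lambda k: (k[0], str(k[1]))):
        idx = blocks[key]
        freqs = np.array([ms.modes[i].frequency for i in idx])
        evecs = np.stack([ms.modes[i].eigenvector for i in idx], axis=1)

        # pairwise mixing inside near-degenerate clusters
        if theta > 0:
            order = np.argsort(freqs, kind="stable")
            cluster: List[int] = []
            clusters: List[List[int]] = []
            for pos in order:
                if cluster and freqs[pos] - freqs[cluster[-1]] > cluster_gap:
                    clusters.append(cluster)
                    cluster = []
                cluster.append(pos)
            if cluster:
                clusters.append(cluster)
            c, s = np.cos(theta), np.sin(theta)
            for cl in clusters:
                for a, b in zip(cl[0::2], cl[1::2]):
                    ea, eb = evecs[:, a].copy(), evecs[:, b].copy()
                    evecs[:, a] = c * ea + s * eb
                    evecs[:, b] = -s * ea + c * eb

        noisy = freqs * spec.freq_scale * (
            1.0 + rng.normal(0.0, spec.freq_noise_sd, size=freqs.size)
        )
        perm = rng.permutation(len(idx))
        for slot, src in zip(idx, perm):
            m_src = ms.modes[idx[src]]
            new_modes[slot] = PhononMode(
                frequency=float(noisy[src]),
                qpoint_index=m_src.qpoint_index,
                eigenvector=evecs[:, src].copy(),
                irrep=m_src.irrep,
                raman_tensor=None
                if m_src.raman_tensor is None
                else m_src.raman_tensor.copy(),
                is_translation=False,
            )
            truth[slot] = idx[src]

    cell = CrystalCell(
        label=ms.cell.label,
        volume=ms.cell.volume,
        z_formula=ms.cell.z_formula,
        e_electronic=ms.cell.e_electronic + spec.energy_shift * ms.cell.z_formula,
        method=ms.cell.method + "+perturbed",
    )
    out = ModeSet(
        cell=cell,
        n_atoms=ms.n_atoms,
        symbols=list(ms.symbols),
        masses=ms.masses.copy(),
        qpoints=list(ms.qpoints),
        modes=new_modes,
    )
    return out, truth


def replace_mode(m: PhononMode) -> PhononMode:
    """Deep copy of a mode (arrays copied)."""
    return PhononMode(
        frequency=m.frequency,
        qpoint_index=m.qpoint_index,
        eigenvector=m.eigenvector.copy(),
        irrep=m.irrep,
        raman_tensor=None if m.raman_tensor is None else m.raman_tensor.copy(),
        is_translation=m.is_translation,
    )
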