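"""Domain types, file format and validators for per-polymorph phonon data.

A :class:`ModeSet` bundles everything the downstream stages need about one
polymorph computed with one method: cell metadata (volume, formula units,
electronic energy), the atoms (symbols and masses, which fix the meaning of
the eigenvector components), the q-point sampling of the Brillouin zone,
and the phonon modes themselves.

Conventions
-----------
* Frequencies are wavenumbers in cm^-1.  Imaginary modes are encoded as
  negative wavenumbers, the usual phonon-code convention.
* Eigenvectors are mass-weighted Cartesian displacements, real-valued
  (Gamma and commensurate q-points only) and unit-normalized, stored as a
  flat vector of 3N components ordered ``(atom0_x, atom0_y, atom0_z, ...)``.
  Complex eigenvectors are rejected at load time.
* Energies are kJ/mol per cell; per-formula reporting divides by the number
  of formula units ``z_formula``.
* Atom ordering is part of the file contract.  Two mode sets are comparable
  only when their atom checksums (symbols + masses) agree.

The on-disk format is a single JSON document with top-level keys
``cell``, ``atoms``, ``qpoints`` and ``modes`` (see :func:`save_modeset`).
Serialization uses sorted keys and ``repr``-exact floats, so saving the
same ModeSet twice produces byte-identical files and frequencies round-trip
at full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CrystalCell",
    "PhononMode",
    "QPoint",
    "ModeSet",
    "ThermoReport",
    "ModeSetParseError",
    "ModeSetValidationError",
    "IncomparableSetsError",
    "load_modeset",
    "save_modeset",
    "load_phonopy_mesh",
    "validate_modeset",
    "validate_for_thermo",
    "translation_basis",
    "translation_residual",
]

#: |frequency| below this (cm^-1) is a candidate acoustic/translational mode.
TRANSLATION_FREQ_TOL = 0.1
#: Residual of the eigenvector outside the rigid-translation subspace.
TRANSLATION_EVEC_TOL = 1e-3

_EVEC_NORM_TOL = 1e-8
_TENSOR_SYM_TOL = 1e-8
_WEIGHT_SUM_TOL = 1e-10
_ORTHO_TOL = 1e-6


class ModeSetParseError(ValueError):
    """A mode-set file is structurally malformed (missing/ill-typed record)."""


class ModeSetValidationError(ValueError):
    """A parsed mode set violates one or more physical invariants."""

    def __init__(self, failures: Sequence[str]):
        self.failures = list(failures)
        super().__init__(
            "mode set failed validation:\n  - " + "\n  - ".join(self.failures)
        )


class IncomparableSetsError(ValueError):
    """Two mode sets cannot be compared (different atoms or ordering)."""


@dataclass(frozen=True)
class CrystalCell:
    """Static cell metadata of one polymorph computed by one method."""

    label: str
    volume: float            # cell volume, Angstrom^3
    z_formula: int           # formula units per cell
    e_electronic: float      # electronic energy E_DFT, kJ/mol per cell
    method: str = ""         # free-text method tag, e.g. "PBE/def2-TZVP"

    def __post_init__(self):
        if not self.volume > 0:
            raise ValueError(f"cell volume must be positive, got {self.volume}")
        if int(self.z_formula) != self.z_formula or self.z_formula < 1:
            raise ValueError(f"z_formula must be a positive integer, got {self.z_formula}")


@dataclass(frozen=True)
class QPoint:
    """One sampling point of the Brillouin zone with its quadrature weight."""

    index: int
    coordinates: tuple  # 3 fractional reciprocal coordinates
    weight: float

    def __post_init__(self):
        if len(self.coordinates) != 3:
            raise ValueError("q-point needs 3 fractional coordinates")
        if self.weight < 0:
            raise ValueError("q-point weight must be nonnegative")

    @property
    def is_gamma(self) -> bool:
        return all(abs(c) < 1e-12 for c in self.coordinates)


@dataclass
class PhononMode:
    """One phonon mode: frequency + eigenvector at one q-point.

    ``frequency`` is a wavenumber in cm^-1; negative values encode imaginary
    modes.  ``raman_tensor`` is the symmetric 3x3 polarizability-derivative
    tensor in arbitrary consistent units, present only when the mode's Raman
    activity has been computed (Gamma-point modes).
    """

    frequency: float
    qpoint_index: int
    eigenvector: np.ndarray
    irrep: Optional[str] = None
    raman_tensor: Optional[np.ndarray] = None
    is_translation: bool = False

    def __post_init__(self):
        self.eigenvector = np.asarray(self.eigenvector, dtype=float)
        if self.raman_tensor is not None:
            self.raman_tensor = np.asarray(self.raman_tensor, dtype=float)

    @property
    def is_imaginary(self) -> bool:
        return self.frequency < 0


@dataclass
class ModeSet:
    """All phonon modes of one polymorph computed by one method."""

    cell: CrystalCell
    n_atoms: int
    symbols: list
    masses: np.ndarray      # amu, one per atom
    qpoints: list           # of QPoint
    modes: list             # of PhononMode

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)

    # -- basic views ---------------------------------------------------

    def modes_at(self, qpoint_index: int):
        return [m for m in self.modes if m.qpoint_index == qpoint_index]

    @property
    def gamma_index(self) -> int:
        for q in self.qpoints:
            if q.is_gamma:
                return q.index
        raise ValueError("mode set has no Gamma point")

    def gamma_modes(self, include_translations: bool = True):
        ms = self.modes_at(self.gamma_index)
        if include_translations:
            return ms
        return [m for m in ms if not m.is_translation]

    def nontranslational_modes(self):
        return [m for m in self.modes if not m.is_translation]

    @property
    def atom_checksum(self) -> str:
        """SHA-256 over atom symbols and masses; the comparability token."""
        payload = "|".join(
            f"{s}:{m:.6f}" for s, m in zip(self.symbols, self.masses)
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def require_comparable(self, other: "ModeSet") -> None:
        if self.n_atoms != other.n_atoms:
            raise IncomparableSetsError(
                f"atom counts differ: {self.n_atoms} vs {other.n_atoms}"
            )
        if self.atom_checksum != other.atom_checksum:
            raise IncomparableSetsError(
                "atom checksums differ: the sets have different atoms or ordering"
            )


# ---------------------------------------------------------------------------
# Rigid translations


def translation_basis(masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N x 3) of mass-weighted rigid translations.

    In mass-weighted coordinates a uniform translation along axis ``a`` has
    components sqrt(m_i) on every atom's ``a`` component; the three axes give
    mutually orthogonal vectors, normalized here to unit length.
    """
    masses = np.asarray(masses, dtype=float)
    n = masses.size
    basis = np.zeros((3 * n, 3))
    root_m = np.sqrt(masses)
    for axis in range(3):
        basis[axis::3, axis] = root_m
    basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def translation_residual(eigenvector: np.ndarray, masses: np.ndarray) -> float:
    """Norm of the eigenvector component outside the rigid-translation subspace."""
    basis = translation_basis(masses)
    e = np.asarray(eigenvector, dtype=float)
    return float(np.linalg.norm(e - basis @ (basis.T @ e)))


def looks_translational(
    mode: PhononMode,
    masses: np.ndarray,
    freq_tol: float = TRANSLATION_FREQ_TOL,
    evec_tol: float = TRANSLATION_EVEC_TOL,
) -> bool:
    """Acoustic test at Gamma: near-zero frequency AND translation-like
    eigenvector.  Both criteria are required."""
    if abs(mode.frequency) >= freq_tol:
        return False
    return translation_residual(mode.eigenvector, masses) < evec_tol


# ---------------------------------------------------------------------------
# Validation


def validate_modeset(ms: ModeSet) -> list:
    """Collect invariant violations; an empty list means the set is valid."""
    failures = []
    if ms.n_atoms < 1:
        failures.append(f"n_atoms must be positive, got {ms.n_atoms}")
    if len(ms.symbols) != ms.n_atoms or ms.masses.size != ms.n_atoms:
        failures.append(
            f"atoms block has {len(ms.symbols)} symbols / {ms.masses.size} masses, "
            f"expected {ms.n_atoms}"
        )
    if np.any(ms.masses <= 0):
        failures.append("atomic masses must be positive")

    wsum = sum(q.weight for q in ms.qpoints)
    if abs(wsum - 1.0) > _WEIGHT_SUM_TOL:
        failures.append(f"q-point weights sum to {wsum!r}, expected 1")

    n_expected = 3 * ms.n_atoms
    for q in ms.qpoints:
        got = len(ms.modes_at(q.index))
        if got != n_expected:
            failures.append(
                f"q-point {q.index} carries {got} modes, expected 3N = {n_expected}"
            )

    for k, m in enumerate(ms.modes):
        if m.eigenvector.size != n_expected:
            failures.append(
                f"mode {k}: eigenvector has {m.eigenvector.size} components, "
                f"expected {n_expected}"
            )
            continue
        if np.iscomplexobj(m.eigenvector):
            failures.append(f"mode {k}: complex eigenvectors are not supported")
            continue
        nrm = np.linalg.norm(m.eigenvector)
        if abs(nrm - 1.0) > _EVEC_NORM_TOL:
            failures.append(f"mode {k}: eigenvector norm {nrm!r} != 1")
        if m.raman_tensor is not None:
            t = m.raman_tensor
            if t.shape != (3, 3):
                failures.append(f"mode {k}: Raman tensor shape {t.shape} != (3, 3)")
            elif np.max(np.abs(t - t.T)) > _TENSOR_SYM_TOL:
                failures.append(f"mode {k}: Raman tensor is not symmetric")

    # Gamma must carry exactly 3 translational modes
    try:
        gidx = ms.gamma_index
    except ValueError:
        gidx = None
    if gidx is not None:
        n_trans = sum(1 for m in ms.modes_at(gidx) if m.is_translation)
        if n_trans != 3:
            failures.append(
                f"Gamma block flags {n_trans} translational modes, expected exactly 3"
            )

    # orthogonality within each (q, irrep) block
    for q in ms.qpoints:
        block_modes = ms.modes_at(q.index)
        by_irrep: dict = {}
        for m in block_modes:
            by_irrep.setdefault(m.irrep, []).append(m)
        for irrep, group in by_irrep.items():
            if len(group) < 2:
                continue
            if any(m.eigenvector.size != n_expected for m in group):
                continue
            evecs = np.stack([m.eigenvector for m in group])
            gram = evecs @ evecs.T
            off = np.max(np.abs(gram - np.diag(np.diag(gram))))
            if off > _ORTHO_TOL:
                failures.append(
                    f"q-point {q.index}, irrep {irrep!r}: eigenvectors are not "
                    f"mutually orthogonal (max |dot| = {off:.2e})"
                )
    return failures


@dataclass
class ThermoReport:
    """Report of :func:`validate_for_thermo`; never mutates the mode set."""

    imaginary: list = field(default_factory=list)          # indices with freq < -tol
    near_zero_nonacoustic: list = field(default_factory=list)
    classified_translational: list = field(default_factory=list)
    weight_sum_deviation: float = 0.0

    @property
    def thermo_ready(self) -> bool:
        return not self.imaginary and self.weight_sum_deviation <= _WEIGHT_SUM_TOL

    @property
    def clean(self) -> bool:
        return (
            self.thermo_ready
            and not self.near_zero_nonacoustic
            and not self.classified_translational
        )


def validate_for_thermo(ms: ModeSet, freq_tol: float = TRANSLATION_FREQ_TOL) -> ThermoReport:
    """Check a mode set for thermodynamic use (report-only, pure).

    Flags imaginary nontranslational modes (frequency < -freq_tol), near-zero
    modes that are not flagged translational (classifying those whose
    eigenvector passes the rigid-translation test), and any deviation of the
    q-weight sum from 1.  A set with imaginary nontranslational modes is not
    thermo-ready.
    """
    report = ThermoReport()
    report.weight_sum_deviation = abs(sum(q.weight for q in ms.qpoints) - 1.0)
    for k, m in enumerate(ms.modes):
        if m.is_translation:
            continue
        if m.frequency < -freq_tol:
            report.imaginary.append(k)
        elif abs(m.frequency) < freq_tol:
            if looks_translational(m, ms.masses, freq_tol=freq_tol):
                report.classified_translational.append(k)
            else:
                report.near_zero_nonacoustic.append(k)
    return report


# ---------------------------------------------------------------------------
# I/O


def _mode_to_record(m: PhononMode) -> dict:
    rec = {
        "q": m.qpoint_index,
        "frequency_cm1": m.frequency,
        "irrep": m.irrep,
        "is_translation": m.is_translation,
        "eigenvector": [float(x) for x in m.eigenvector],
        "raman_tensor": None
        if m.raman_tensor is None
        else [[float(x) for x in row] for row in m.raman_tensor],
    }
    return rec


def save_modeset(ms: ModeSet, path) -> None:
    """Write a mode set as JSON.

    The document uses sorted keys and exact float repr, so two saves of the
    same ModeSet are byte-identical and all floats round-trip exactly.
    """
    failures = validate_modeset(ms)
    if failures:
        raise ModeSetValidationError(failures)
    doc = {
        "cell": {
            "label": ms.cell.label,
            "volume_A3": ms.cell.volume,
            "z_formula": ms.cell.z_formula,
            "e_electronic_kjmol": ms.cell.e_electronic,
            "method": ms.cell.method,
        },
        "atoms": {
            "symbols": list(ms.symbols),
            "masses_amu": [float(m) for m in ms.masses],
        },
        "qpoints": [
            {"coords": [float(c) for c in q.coordinates], "weight": float(q.weight)}
            for q in sorted(ms.qpoints, key=lambda q: q.index)
        ],
        "modes": [_mode_to_record(m) for m in ms.modes],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise ModeSetParseError(f"missing key {key!r} in {where}")
    return doc[key]


def load_modeset(path) -> ModeSet:
    """Read and validate a mode-set JSON file.

    Raises :class:`ModeSetParseError` for malformed documents (naming the
    offending record) and :class:`ModeSetValidationError` listing every
    violated invariant otherwise.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModeSetParseError(f"not valid JSON: {exc}") from exc

    cell_doc = _require(doc, "cell", "document root")
    atoms_doc = _require(doc, "atoms", "document root")
    qp_doc = _require(doc, "qpoints", "document root")
    modes_doc = _require(doc, "modes", "document root")

    try:
        cell = CrystalCell(
            label=str(_require(cell_doc, "label", "cell")),
            volume=float(_require(cell_doc, "volume_A3", "cell")),
            z_formula=int(_require(cell_doc, "z_formula", "cell")),
            e_electronic=float(_require(cell_doc, "e_electronic_kjmol", "cell")),
            method=str(cell_doc.get("method", "")),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ModeSetParseError):
            raise
        raise ModeSetParseError(f"malformed cell record: {exc}") from exc

    symbols = list(_require(atoms_doc, "symbols", "atoms"))
    masses = _require(atoms_doc, "masses_amu", "atoms")

    qpoints = []
    for i, q in enumerate(qp_doc):
        try:
            qpoints.append(
                QPoint(
                    index=i,
                    coordinates=tuple(float(c) for c in _require(q, "coords", f"qpoints[{i}]")),
                    weight=float(_require(q, "weight", f"qpoints[{i}]")),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ModeSetParseError):
                raise
            raise ModeSetParseError(f"malformed q-point record {i}: {exc}") from exc

    modes = []
    for i, rec in enumerate(modes_doc):
        try:
            evec = np.asarray(_require(rec, "eigenvector", f"modes[{i}]"), dtype=float)
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ModeSetParseError):
                raise
            raise ModeSetParseError(
                f"malformed eigenvector in modes[{i}]: {exc}"
            ) from exc
        tensor = rec.get("raman_tensor")
        try:
            modes.append(
                PhononMode(
                    frequency=float(_require(rec, "frequency_cm1", f"modes[{i}]")),
                    qpoint_index=int(_require(rec, "q", f"modes[{i}]")),
                    eigenvector=evec,
                    irrep=rec.get("irrep"),
                    raman_tensor=None if tensor is None else np.asarray(tensor, float),
                    is_translation=bool(rec.get("is_translation", False)),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ModeSetParseError):
                raise
            raise ModeSetParseError(f"malformed mode record {i}: {exc}") from exc

    ms = ModeSet(
        cell=cell,
        n_atoms=len(symbols),
        symbols=symbols,
        masses=np.asarray(masses, dtype=float),
        qpoints=qpoints,
        modes=modes,
    )
    failures = validate_modeset(ms)
    if failures:
        raise ModeSetValidationError(failures)
    return ms


# THz (ordinary, as written by lattice-dynamics mesh files) -> cm^-1
_THZ_TO_CM1 = 1e12 / 29979245800.0


def load_phonopy_mesh(path, cell: CrystalCell, freq_unit: str = "THz") -> ModeSet:
    """Best-effort importer for a phonopy-style ``mesh.yaml`` document.

    Maps the mesh layout (``natom``, ``points`` with symbol/mass,
    ``phonon`` blocks with q-position, integer weight and per-band
    frequency + eigenvector) onto a :class:`ModeSet`.  The mesh file
    carries no cell energetics, so the caller supplies the
    :class:`CrystalCell`.  Frequencies in THz are converted to cm^-1;
    eigenvectors must be real within 1e-8 (commensurate q only) and are
    renormalized to unit length.  Integer weights are normalized to sum
    to 1.  Translational modes at Gamma are identified with the standard
    frequency + eigenvector test; if that yields anything but exactly 3,
    the three lowest-|frequency| Gamma modes are flagged instead.

    Any missing or ill-shaped field raises :class:`ModeSetParseError`
    naming the offender — failures are explicit, never silent.
    """
    import yaml

    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ModeSetParseError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModeSetParseError("mesh document is not a mapping")

    natom = _require(doc, "natom", "document root")
    points = _require(doc, "points", "document root")
    if len(points) != natom:
        raise ModeSetParseError(
            f"points block has {len(points)} entries, natom says {natom}"
        )
    symbols = [str(_require(p, "symbol", f"points[{i}]")) for i, p in enumerate(points)]
    masses = np.array(
        [float(_require(p, "mass", f"points[{i}]")) for i, p in enumerate(points)]
    )

    phonon = _require(doc, "phonon", "document root")
    raw_weights = []
    qpoints = []
    modes: list = []
    for iq, block in enumerate(phonon):
        coords = tuple(
            float(c) for c in _require(block, "q-position", f"phonon[{iq}]")
        )
        raw_weights.append(float(block.get("weight", 1.0)))
        qpoints.append(QPoint(index=iq, coordinates=coords, weight=0.0))
        bands = _require(block, "band", f"phonon[{iq}]")
        if len(bands) != 3 * natom:
            raise ModeSetParseError(
                f"phonon[{iq}] carries {len(bands)} bands, expected {3 * natom}"
            )
        for ib, band in enumerate(bands):
            where = f"phonon[{iq}].band[{ib}]"
            freq = float(_require(band, "frequency", where))
            if freq_unit == "THz":
                freq *= _THZ_TO_CM1
            elif freq_unit != "cm-1":
                raise ModeSetParseError(f"unsupported frequency unit {freq_unit!r}")
            ev_raw = np.asarray(_require(band, "eigenvector", where), dtype=float)
            if ev_raw.shape != (natom, 3, 2):
                raise ModeSetParseError(
                    f"{where}: eigenvector shape {ev_raw.shape}, "
                    f"expected ({natom}, 3, 2) [re, im] components"
                )
            if np.max(np.abs(ev_raw[..., 1])) > 1e-8:
                raise ModeSetParseError(
                    f"{where}: complex eigenvector (only commensurate real "
                    "eigenvectors are supported)"
                )
            ev = ev_raw[..., 0].reshape(-1)
            nrm = np.linalg.norm(ev)
            if nrm == 0:
                raise ModeSetParseError(f"{where}: zero eigenvector")
            modes.append(
                PhononMode(
                    frequency=freq,
                    qpoint_index=iq,
                    eigenvector=ev / nrm,
                )
            )

    wsum = sum(raw_weights)
    if wsum <= 0:
        raise ModeSetParseError("q-point weights sum to zero")
    qpoints = [
        QPoint(index=q.index, coordinates=q.coordinates, weight=w / wsum)
        for q, w in zip(qpoints, raw_weights)
    ]

    ms = ModeSet(
        cell=cell,
        n_atoms=int(natom),
        symbols=symbols,
        masses=masses,
        qpoints=qpoints,
        modes=modes,
    )
    # flag the Gamma translations
    try:
        gidx = ms.gamma_index
    except ValueError:
        gidx = None
    if gidx is not None:
        gmodes = [(k, m) for k, m in enumerate(ms.modes) if m.qpoint_index == gidx]
        flagged = [k for k, m in gmodes if looks_translational(m, masses)]
        if len(flagged) != 3:
            flagged = sorted(gmodes, key=lambda km: abs(km[1].frequency))[:3]
            flagged = [k for k, _ in flagged]
        for k in flagged:
            ms.modes[k].is_translation = True
    failures = validate_modeset(ms)
    if failures:
        raise ModeSetValidationError(failures)
    return ms
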