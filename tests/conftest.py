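import numpy as np
import pytest

from phonorank import generate_modeset, generate_polymorph_pair
from phonorank.mode_data import (
    CrystalCell,
    ModeSet,
    PhononMode,
    QPoint,
    translation_basis,
)
from phonorank.synthetic_data import DEFAULT_BANDS


@pytest.fixture
def small_modeset():
    """One small valid polymorph: 8 atoms, 24 modes, single Gamma point."""
    return generate_modeset(
        n_atoms=8,
        label="alpha",
        z_formula=4,
        volume=741.2,
        e_electronic_per_formula=-1.0e5,
        bands=DEFAULT_BANDS,
        n_qpoints=1,
        seed=11,
    )


@pytest.fixture
def polymorph_pair():
    return generate_polymorph_pair(n_atoms=10, n_qpoints=1, seed=42)


def make_gamma_modeset(frequencies, raman_tensors=None, masses=None, **cell_kw):
    """Hand-built Gamma-only ModeSet with the given nontranslational
    frequencies; eigenvectors are an exact orthonormal completion of the
    rigid translations."""
    n_opt = len(frequencies)
    n_atoms = (n_opt + 3) // 3 + (1 if (n_opt + 3) % 3 else 0)
    n_modes = 3 * n_atoms
    if masses is None:
        masses = np.linspace(1.0, 16.0, n_atoms)
    masses = np.asarray(masses, float)
    trans = translation_basis(masses)
    rng = np.random.default_rng(987)
    gauss = rng.standard_normal((n_modes, n_modes - 3))
    q, r = np.linalg.qr(np.hstack([trans, gauss]))
    q = q * np.sign(np.diag(r))
    cell = CrystalCell(
        label=cell_kw.pop("label", "fab"),
        volume=cell_kw.pop("volume", 700.0),
        z_formula=cell_kw.pop("z_formula", 1),
        e_electronic=cell_kw.pop("e_electronic", -1000.0),
        method=cell_kw.pop("method", "fabricated"),
    )
    modes = [
        PhononMode(
            frequency=0.0,
            qpoint_index=0,
            eigenvector=q[:, k],
            is_translation=True,
        )
        for k in range(3)
    ]
    for k in range(n_opt):
        tensor = None
        if raman_tensors is not None:
            tensor = raman_tensors[k]
        modes.append(
            PhononMode(
                frequency=float(frequencies[k]),
                qpoint_index=0,
                eigenvector=q[:, 3 + k],
                raman_tensor=tensor,
            )
        )
    # pad with inactive high-frequency modes so each q carries 3N modes
    for k in range(n_opt, n_modes - 3):
        modes.append(
            PhononMode(
                frequency=3000.0 + k,
                qpoint_index=0,
                eigenvector=q[:, 3 + k],
            )
        )
    return ModeSet(
        cell=cell,
        n_atoms=n_atoms,
        symbols=["C"] * n_atoms,
        masses=masses,
        qpoints=[QPoint(index=0, coordinates=(0.0, 0.0, 0.0), weight=1.0)],
        modes=modes,
    )


@pytest.fixture
def single_line_modeset():
    """One Raman-active 100 cm^-1 mode with a unit tensor; everything else
    inactive."""
    return make_gamma_modeset([100.0], raman_tensors=[np.eye(3)])
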