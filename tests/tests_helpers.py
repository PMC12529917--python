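"""Hand-constructed fixtures shared by a few test modules."""

import numpy as np

from phonorank.mode_data import CrystalCell, ModeSet, PhononMode, QPoint, translation_basis


def degenerate_pair_modeset():
    """Gamma-only set whose nontranslational modes include an exactly
    degenerate pair at 100 cm^-1; eigenvectors are an exact orthonormal
    completion of the rigid translations."""
    n_atoms = 3
    masses = np.array([12.011, 1.008, 15.999])
    trans = translation_basis(masses)
    rng = np.random.default_rng(55)
    gauss = rng.standard_normal((9, 6))
    q, r = np.linalg.qr(np.hstack([trans, gauss]))
    q = q * np.sign(np.diag(r))
    freqs = [100.0, 100.0, 300.0, 500.0, 900.0, 3000.0]
    modes = [
        PhononMode(0.0, 0, q[:, k], is_translation=True) for k in range(3)
    ] + [
        PhononMode(f, 0, q[:, 3 + k]) for k, f in enumerate(freqs)
    ]
    return ModeSet(
        cell=CrystalCell("degenerate", 100.0, 1, -100.0, "fabricated"),
        n_atoms=n_atoms,
        symbols=["C", "H", "O"],
        masses=masses,
        qpoints=[QPoint(0, (0.0, 0.0, 0.0), 1.0)],
        modes=modes,
    )
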