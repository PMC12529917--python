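import copy

import numpy as np
import pytest

from phonorank import (
    ScalingScheme,
    apply_scaling,
    gibbs_free_energy,
    mode_free_energy,
    partition_delta_f,
)
from phonorank.thermo import (
    DEFAULT_PARTITION_BANDS,
    SCALING_FACTOR_REGISTRY,
    _mode_free_energy_terms,
    scheme_for_method,
)
from phonorank import units

from conftest import make_gamma_modeset


class TestScaling:
    def test_registry_paw_entry_is_identity(self, small_modeset):
        scheme = scheme_for_method("PAW/PBE")
        assert scheme.factor == 1.0
        scaled = apply_scaling(small_modeset, scheme)
        for m0, m1 in zip(small_modeset.modes, scaled.modes):
            assert m1.frequency == m0.frequency

    def test_below_threshold_unchanged(self):
        ms = make_gamma_modeset([100.0, 3000.0])
        scaled = apply_scaling(ms, ScalingScheme(factor=0.95))
        freqs = sorted(m.frequency for m in scaled.nontranslational_modes())
        assert freqs[0] == 100.0

    def test_hybrid_triple_zeta_factor(self):
        # 3000 cm^-1 under the 0.9591 hybrid/def2-TZVP factor
        ms = make_gamma_modeset([3000.0])
        scaled = apply_scaling(ms, scheme_for_method("PBE0/def2-TZVP"))
        freqs = [m.frequency for m in scaled.nontranslational_modes()]
        assert min(freqs) == pytest.approx(2877.3, abs=1e-9)

    def test_eigenvectors_untouched(self, small_modeset):
        scaled = apply_scaling(small_modeset, ScalingScheme(factor=0.9))
        for m0, m1 in zip(small_modeset.modes, scaled.modes):
            np.testing.assert_array_equal(m1.eigenvector, m0.eigenvector)

    def test_registry_has_all_method_basis_combinations(self):
        assert len(SCALING_FACTOR_REGISTRY) == 9
        with pytest.raises(KeyError):
            scheme_for_method("HF/STO-3G")


class TestModeFreeEnergy:
    def test_zero_temperature_is_zero_point_exactly(self):
        # independent oracle: N_A * h * c * (100 cm^-1) / 2 = 0.598132828 kJ/mol
        assert mode_free_energy(100.0, 0.0) == pytest.approx(
            0.598132828193485, rel=1e-12
        )
        zp, th = _mode_free_energy_terms(100.0, 0.0)
        assert th == 0.0

    def test_classical_limit(self):
        # at k_B T / hbar omega = 100 the thermal term approaches
        # k_B T ln(hbar omega / k_B T) within 1%
        freq = 100.0
        hbar_omega = units.HBAR * float(units.wavenumber_to_angular(freq))
        t = 100.0 * hbar_omega / units.K_B
        _, thermal = _mode_free_energy_terms(freq, t)
        classical = units.N_A * units.K_B * t * np.log(hbar_omega / (units.K_B * t)) / 1e3
        assert thermal == pytest.approx(classical, rel=1e-2)

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_nonpositive_frequency_rejected(self, bad):
        with pytest.raises(ValueError):
            mode_free_energy(bad, 300.0)

    def test_zero_point_independent_of_temperature(self):
        zp1, _ = _mode_free_energy_terms(500.0, 0.0)
        zp2, _ = _mode_free_energy_terms(500.0, 400.0)
        assert zp1 == zp2


class TestGibbs:
    def test_zero_mode_limit(self):
        # fabricate a set whose only optical modes are inactive but present;
        # compare F to E + ZPE + pV assembled by hand
        ms = make_gamma_modeset([100.0, 200.0], z_formula=2)
        surf = gibbs_free_energy(ms, [0.0], pressure=100.0)
        z = ms.cell.z_formula
        zpe = sum(
            mode_free_energy(m.frequency, 0.0)
            for m in ms.nontranslational_modes()
        )
        expected = (
            ms.cell.e_electronic
            + zpe
            + 100.0 * ms.cell.volume * units.KJMOL_PER_MPA_A3
        ) / z
        assert surf.f[0, 0] == pytest.approx(expected, rel=1e-12)
        assert surf.thermal[0] == 0.0

    def test_decomposition_identity(self, small_modeset):
        surf = gibbs_free_energy(small_modeset, [0.0, 150.0, 298.0], pressure=50.0)
        rebuilt = (
            surf.electronic + surf.zero_point + surf.thermal[:, None] + surf.pv[None, :]
        )
        np.testing.assert_allclose(surf.f, rebuilt, atol=1e-9)

    def test_duplicated_qpoints_leave_f_unchanged(self, small_modeset):
        from phonorank.mode_data import ModeSet, PhononMode, QPoint

        ms = small_modeset
        two_q = copy.deepcopy(ms)
        two_q.qpoints = [
            QPoint(0, (0.0, 0.0, 0.0), 0.5),
            QPoint(1, (0.25, 0.0, 0.0), 0.5),
        ]
        extra = []
        for m in ms.modes:
            dup = copy.deepcopy(m)
            dup.qpoint_index = 1
            dup.is_translation = False
            if dup.frequency < 0.1:
                dup.frequency = 0.05  # acoustic away from Gamma, excluded by tol
            extra.append(dup)
        two_q.modes = [copy.deepcopy(m) for m in ms.modes] + extra
        f_one = gibbs_free_energy(ms, [0.0, 300.0])
        f_two = gibbs_free_energy(two_q, [0.0, 300.0])
        np.testing.assert_allclose(f_two.f, f_one.f, atol=1e-9)

    def test_imaginary_mode_refused_with_list(self, small_modeset):
        ms = copy.deepcopy(small_modeset)
        ms.modes[5].frequency = -12.0
        with pytest.raises(ValueError, match=r"imaginary.*\[5\]"):
            gibbs_free_energy(ms, [0.0])

    def test_f_nonincreasing_in_temperature(self, polymorph_pair):
        t_grid = np.linspace(0.0, 400.0, 21)
        for ms in polymorph_pair:
            surf = gibbs_free_energy(ms, t_grid)
            assert np.all(np.diff(surf.f[:, 0]) <= 0)

    def test_per_formula_invariant_under_cell_doubling(self, small_modeset):
        # a supercell with doubled z, E_DFT, V and every mode duplicated has
        # the same per-formula free energy
        from phonorank.mode_data import CrystalCell

        doubled = copy.deepcopy(small_modeset)
        doubled.cell = CrystalCell(
            label=doubled.cell.label,
            volume=doubled.cell.volume * 2,
            z_formula=doubled.cell.z_formula * 2,
            e_electronic=doubled.cell.e_electronic * 2,
            method=doubled.cell.method,
        )
        doubled.n_atoms = doubled.n_atoms * 2
        doubled.modes = doubled.modes + [copy.deepcopy(m) for m in doubled.modes]
        f_orig = gibbs_free_energy(small_modeset, [0.0, 300.0], pressure=50.0)
        f_doub = gibbs_free_energy(doubled, [0.0, 300.0], pressure=50.0)
        np.testing.assert_allclose(f_doub.f, f_orig.f, rtol=1e-12)


class TestPartition:
    def test_identical_polymorphs_all_zero(self, small_modeset):
        t_grid = [0.0, 298.0]
        surf = gibbs_free_energy(small_modeset, t_grid)
        part = partition_delta_f(
            surf, surf, small_modeset, small_modeset, temperature=298.0
        )
        assert part.delta_f_dft == 0.0
        assert part.delta_f_total == 0.0
        for v in part.delta_f_per_band.values():
            assert v == 0.0

    def test_low_band_only_fixture(self):
        lo_a = make_gamma_modeset([50.0, 120.0, 200.0], label="a")
        lo_b = make_gamma_modeset([60.0, 110.0, 190.0], label="b")
        # both fabricated cells carry optical modes below 250 cm^-1 only
        t_grid = [0.0, 298.0]
        fa = gibbs_free_energy(lo_a, t_grid)
        fb = gibbs_free_energy(lo_b, t_grid)
        part = partition_delta_f(fa, fb, lo_a, lo_b, temperature=298.0)
        assert part.delta_f_per_band["medium"] == pytest.approx(0.0, abs=1e-12)
        assert part.delta_f_per_band["high"] == pytest.approx(0.0, abs=1e-12)
        assert part.delta_f_per_band["gap"] == pytest.approx(0.0, abs=1e-12)
        assert part.delta_f_per_band["low"] == pytest.approx(
            part.delta_f_total - part.delta_f_dft, abs=1e-9
        )

    @pytest.mark.parametrize("temperature", [0.0, 298.0])
    def test_components_sum_to_total(self, polymorph_pair, temperature):
        a, b = polymorph_pair
        t_grid = [0.0, 298.0]
        fa = gibbs_free_energy(a, t_grid)
        fb = gibbs_free_energy(b, t_grid)
        part = partition_delta_f(fa, fb, a, b, temperature=temperature)
        assert abs(part.residual) < 1e-9

    def test_scaled_partition_still_conserves(self, polymorph_pair):
        a, b = polymorph_pair
        scheme = ScalingScheme(factor=0.9591)
        t_grid = [298.0]
        fa = gibbs_free_energy(a, t_grid, scheme=scheme)
        fb = gibbs_free_energy(b, t_grid, scheme=scheme)
        part = partition_delta_f(
            fa, fb, a, b, temperature=298.0, scheme_a=scheme, scheme_b=scheme
        )
        assert abs(part.residual) < 1e-9

    def test_bad_bands_rejected(self, small_modeset):
        surf = gibbs_free_energy(small_modeset, [0.0])
        bad = (("low", 0.0, 250.0), ("high", 300.0, float("inf")))
        with pytest.raises(ValueError, match="partition"):
            partition_delta_f(
                surf, surf, small_modeset, small_modeset, bands=bad, temperature=0.0
            )
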