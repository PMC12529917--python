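import copy

import numpy as np
import pytest

from phonorank import load_modeset, save_modeset, validate_for_thermo
from phonorank.mode_data import (
    CrystalCell,
    ModeSetValidationError,
    ModeSetParseError,
    translation_residual,
    validate_modeset,
)


class TestRoundTrip:
    def test_save_load_identity(self, small_modeset, tmp_path):
        path = tmp_path / "ms.json"
        save_modeset(small_modeset, path)
        loaded = load_modeset(path)
        assert loaded.cell == small_modeset.cell
        assert loaded.symbols == small_modeset.symbols
        np.testing.assert_array_equal(loaded.masses, small_modeset.masses)
        assert len(loaded.modes) == len(small_modeset.modes)
        for m0, m1 in zip(small_modeset.modes, loaded.modes):
            assert m1.frequency == m0.frequency  # full precision
            assert m1.irrep == m0.irrep
            assert m1.is_translation == m0.is_translation
            np.testing.assert_array_equal(m1.eigenvector, m0.eigenvector)
            if m0.raman_tensor is None:
                assert m1.raman_tensor is None
            else:
                np.testing.assert_array_equal(m1.raman_tensor, m0.raman_tensor)
        assert loaded.atom_checksum == small_modeset.atom_checksum

    def test_two_saves_byte_identical(self, small_modeset, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_modeset(small_modeset, p1)
        save_modeset(small_modeset, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_file_names_offender(self, small_modeset, tmp_path):
        import json

        path = tmp_path / "ms.json"
        save_modeset(small_modeset, path)
        doc = json.loads(path.read_text())
        del doc["modes"][5]["frequency_cm1"]
        path.write_text(json.dumps(doc))
        with pytest.raises(ModeSetParseError, match=r"modes\[5\]"):
            load_modeset(path)


class TestInvariants:
    def test_mode_counts(self, polymorph_pair):
        a, _ = polymorph_pair  # n_atoms = 10
        assert len(a.modes) == 30
        assert len(a.nontranslational_modes()) == 27

    def test_wrong_translation_count_rejected(self, small_modeset, tmp_path):
        ms = copy.deepcopy(small_modeset)
        # unflag one of the three rigid translations
        trans = [m for m in ms.modes if m.is_translation]
        trans[0].is_translation = False
        failures = validate_modeset(ms)
        assert any("translational" in f for f in failures)
        with pytest.raises(ModeSetValidationError, match="translational"):
            save_modeset(ms, tmp_path / "bad.json")

    def test_unnormalized_eigenvector_rejected(self, small_modeset):
        ms = copy.deepcopy(small_modeset)
        ms.modes[4].eigenvector = ms.modes[4].eigenvector * 1.5
        failures = validate_modeset(ms)
        assert any("norm" in f for f in failures)

    def test_nonorthogonal_block_rejected(self, small_modeset):
        ms = copy.deepcopy(small_modeset)
        ms.modes[5].eigenvector = ms.modes[6].eigenvector.copy()
        failures = validate_modeset(ms)
        assert any("orthogonal" in f for f in failures)

    def test_asymmetric_tensor_rejected(self, small_modeset):
        ms = copy.deepcopy(small_modeset)
        mode = next(m for m in ms.modes if m.raman_tensor is not None)
        mode.raman_tensor = mode.raman_tensor + np.array(
            [[0, 1e-3, 0], [0, 0, 0], [0, 0, 0]]
        )
        failures = validate_modeset(ms)
        assert any("symmetric" in f for f in failures)

    def test_cell_invariants(self):
        with pytest.raises(ValueError):
            CrystalCell("x", volume=-1.0, z_formula=4, e_electronic=0.0)
        with pytest.raises(ValueError):
            CrystalCell("x", volume=700.0, z_formula=0, e_electronic=0.0)


class TestThermoValidation:
    def test_clean_set_empty_report(self, small_modeset):
        report = validate_for_thermo(small_modeset)
        assert report.clean and report.thermo_ready
        assert report.imaginary == []
        assert report.weight_sum_deviation < 1e-10

    def test_imaginary_mode_flagged(self, small_modeset):
        ms = copy.deepcopy(small_modeset)
        ms.modes[7].frequency = -5.0
        report = validate_for_thermo(ms)
        assert report.imaginary == [7]
        assert not report.thermo_ready

    def test_near_zero_acoustic_classified_translational(self, small_modeset):
        ms = copy.deepcopy(small_modeset)
        trans = [m for m in ms.modes if m.is_translation]
        trans[1].is_translation = False
        trans[1].frequency = 0.05
        report = validate_for_thermo(ms, freq_tol=0.1)
        idx = ms.modes.index(trans[1])
        assert report.classified_translational == [idx]
        assert report.thermo_ready

    def test_validation_is_pure(self, small_modeset):
        before = copy.deepcopy(small_modeset)
        validate_for_thermo(small_modeset)
        validate_modeset(small_modeset)
        for m0, m1 in zip(before.modes, small_modeset.modes):
            assert m1.frequency == m0.frequency
            np.testing.assert_array_equal(m1.eigenvector, m0.eigenvector)


def test_translation_residual_zero_for_exact_translation(small_modeset):
    trans = [m for m in small_modeset.modes if m.is_translation]
    for m in trans:
        assert translation_residual(m.eigenvector, small_modeset.masses) < 1e-12
    optical = small_modeset.nontranslational_modes()[0]
    assert translation_residual(optical.eigenvector, small_modeset.masses) > 0.9


class TestPhonopyStyleImporter:
    @staticmethod
    def _write_mesh(ms, path, mangle=None):
        """Serialize a generated ModeSet in the mesh-file layout."""
        import yaml

        cm1_to_thz = 29979245800.0 / 1e12
        doc = {
            "natom": ms.n_atoms,
            "points": [
                {"symbol": s, "mass": float(m), "coordinates": [0.0, 0.0, 0.0]}
                for s, m in zip(ms.symbols, ms.masses)
            ],
            "phonon": [],
        }
        for q in ms.qpoints:
            block = {
                "q-position": list(q.coordinates),
                "weight": 1,
                "band": [],
            }
            for m in ms.modes_at(q.index):
                ev = m.eigenvector.reshape(ms.n_atoms, 3)
                block["band"].append(
                    {
                        "frequency": float(m.frequency * cm1_to_thz),
                        "eigenvector": [
                            [[float(c), 0.0] for c in row] for row in ev
                        ],
                    }
                )
            doc["phonon"].append(block)
        if mangle:
            mangle(doc)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    def test_mesh_import_round_trip(self, small_modeset, tmp_path):
        from phonorank.mode_data import load_phonopy_mesh

        path = tmp_path / "mesh.yaml"
        self._write_mesh(small_modeset, path)
        ms = load_phonopy_mesh(path, small_modeset.cell)
        assert ms.n_atoms == small_modeset.n_atoms
        assert ms.atom_checksum == small_modeset.atom_checksum
        assert sum(m.is_translation for m in ms.modes) == 3
        for m0, m1 in zip(small_modeset.modes, ms.modes):
            assert m1.frequency == pytest.approx(m0.frequency, rel=1e-12)
            np.testing.assert_allclose(m1.eigenvector, m0.eigenvector, atol=1e-12)
        assert validate_modeset(ms) == []

    def test_mesh_import_rejects_complex_eigenvectors(self, small_modeset, tmp_path):
        from phonorank.mode_data import load_phonopy_mesh

        def mangle(doc):
            doc["phonon"][0]["band"][4]["eigenvector"][0][0][1] = 0.3

        path = tmp_path / "mesh.yaml"
        self._write_mesh(small_modeset, path, mangle)
        with pytest.raises(ModeSetParseError, match="complex"):
            load_phonopy_mesh(path, small_modeset.cell)

    def test_mesh_import_names_missing_field(self, small_modeset, tmp_path):
        from phonorank.mode_data import load_phonopy_mesh

        def mangle(doc):
            del doc["phonon"][0]["band"][2]["frequency"]

        path = tmp_path / "mesh.yaml"
        self._write_mesh(small_modeset, path, mangle)
        with pytest.raises(ModeSetParseError, match=r"band\[2\]"):
            load_phonopy_mesh(path, small_modeset.cell)
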