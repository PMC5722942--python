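"""Parsing, insulin identification, curation, and the survey table."""

import numpy as np
import pytest

from insulin_conformers import structure_io
from insulin_conformers.core import Atom, InsulinMonomer, Residue
from insulin_conformers.structure_io import (
    StructureParseError,
    apply_curation_filters,
    identify_insulin_monomers,
    parse_structure,
    read_survey,
    write_survey,
)
from insulin_conformers.synth import (
    build_class_toy,
    monomer_pdb_lines,
    write_monomer_pdb,
)

MINI_PDB = """\
HEADER    TEST
REMARK   2 RESOLUTION.    1.80 ANGSTROMS.
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
END
"""


class TestParsing:
    def test_minimal_single_residue_file(self):
        parsed = parse_structure(MINI_PDB)
        assert len(parsed.models) == 1
        chains = parsed.models[0].chains
        assert len(chains) == 1
        res = chains[0].residues[0]
        assert res.name == "ALA"
        assert {a.name for a in res.atoms} == {"N", "CA", "C", "O"}
        assert parsed.resolution == pytest.approx(1.8)

    def test_multi_model_block_count(self):
        body = MINI_PDB.splitlines()[2:-1]
        text = "\n".join(
            ["HEADER    TEST"]
            + sum([[f"MODEL     {i+1:4d}"] + body + ["ENDMDL"] for i in range(3)], [])
            + ["END"])
        parsed = parse_structure(text)
        assert len(parsed.models) == 3

    def test_unreadable_garbage_raises(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure file")
        with pytest.raises(StructureParseError):
            parse_structure(bad, dialect="mmcif")

    def test_unknown_dialect_rejected(self):
        with pytest.raises(StructureParseError):
            parse_structure(MINI_PDB, dialect="xyz")

    def test_altloc_resolution_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N\n"
            "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.60  0.00           N\n"
            "END\n")
        parsed = parse_structure(text)
        res = parsed.models[0].chains[0].residues[0]
        ns = [a for a in res.atoms if a.name == "N"]
        assert len(ns) == 1
        assert ns[0].coord[0] == pytest.approx(9.0)


class TestIdentification:
    def test_generator_round_trip_labels_and_coords(self, tmp_path, class1_toy):
        path = tmp_path / "toy.pdb"
        write_monomer_pdb(class1_toy, path)
        monomers = identify_insulin_monomers(parse_structure(path))
        assert len(monomers) == 1
        m = monomers[0]
        assert [r.insulin_pos for r in m.a_chain] == [f"A{i}" for i in range(1, 22)]
        assert [r.insulin_pos for r in m.b_chain] == [f"B{i}" for i in range(1, 31)]
        for lab in m.labels():
            # PDB format carries 3 decimals: round trip within 1e-3
            assert np.allclose(m.residue(lab).coord("CA"),
                               class1_toy.residue(lab).coord("CA"), atol=1.01e-3)

    def test_dimer_pairing_by_a7_b7_proximity(self, tmp_path, class1_toy, class2_toy):
        # two monomers in one model, chains A,B (class1) and C,D (class2),
        # the second shifted far away: pairing must follow the construction
        far = class2_toy.transformed(np.eye(3), np.array([80.0, 0.0, 0.0]))
        lines = ["HEADER    DIMR"]
        body1, nxt = monomer_pdb_lines(class1_toy, chain_ids=("A", "B"))
        body2, _ = monomer_pdb_lines(far, chain_ids=("C", "D"), serial_start=nxt)
        path = tmp_path / "dimer.pdb"
        path.write_text("\n".join(lines + body1 + body2 + ["END"]) + "\n")
        monomers = identify_insulin_monomers(parse_structure(path))
        assert len(monomers) == 2
        pairs = {m.source_chain_ids for m in monomers}
        assert pairs == {("A", "B"), ("C", "D")}

    def test_chain_order_permutation_invariance(self, tmp_path, class1_toy, class2_toy):
        far = class2_toy.transformed(np.eye(3), np.array([80.0, 0.0, 0.0]))
        body1, nxt = monomer_pdb_lines(class1_toy, chain_ids=("A", "B"))
        body2, _ = monomer_pdb_lines(far, chain_ids=("C", "D"), serial_start=nxt)
        path = tmp_path / "swapped.pdb"
        path.write_text("\n".join(["HEADER    DIMR"] + body2 + body1 + ["END"]) + "\n")
        monomers = identify_insulin_monomers(parse_structure(path))
        assert {m.source_chain_ids for m in monomers} == {("A", "B"), ("C", "D")}

    def test_no_insulin_chains_gives_empty_list(self):
        parsed = parse_structure(MINI_PDB)
        assert identify_insulin_monomers(parsed) == []


class TestCuration:
    def test_good_monomer_passes(self, class1_toy):
        report = apply_curation_filters(class1_toy, resolution=1.55)
        assert report.passed and report.reasons == []

    def test_resolution_cutoff_is_strict(self, class1_toy):
        report = apply_curation_filters(class1_toy, resolution=2.8)
        assert "resolution_fail" in report.reasons
        ok = apply_curation_filters(class1_toy, resolution=2.79)
        assert "resolution_fail" not in ok.reasons

    def test_bad_ss_bond_length_fails(self, class1_toy):
        report = apply_curation_filters(class1_toy, resolution=1.5,
                                        ss_range=(1.95, 2.03))
        # the toy builds its bridge at 2.04: outside this tightened window
        assert "ss_bond_length_fail" in report.reasons

    def test_dicarba_exempt_from_ss_filter(self):
        m = build_class_toy("CLASS1", bridge_variant="trans_dicarba")
        report = apply_curation_filters(m, resolution=1.55)
        assert "ss_bond_length_fail" not in report.reasons
        assert any("dicarba" in n for n in report.notes)

    def test_exclusion_list(self, class1_toy):
        report = apply_curation_filters(class1_toy, resolution=1.5,
                                        excluded_ids={class1_toy.pdb_id})
        assert "ide_complex_excluded" in report.reasons

    def test_monotone_in_resolution_cutoff(self, class1_toy):
        # tightening the cutoff can only remove passing monomers
        passing = [apply_curation_filters(class1_toy, resolution=2.0,
                                          resolution_cutoff=c).passed
                   for c in (2.8, 2.4, 2.1, 2.0, 1.8)]
        assert passing == sorted(passing, reverse=True)


class TestSurveyTable:
    def test_empty_records_gives_header_only(self, tmp_path):
        path = write_survey([], tmp_path / "empty.tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1

    def test_round_trip_two_rows(self, tmp_path):
        rows = [
            {"pdb_id": "AAAA", "model": 1, "chain": "AB", "class": "CLASS1",
             "ca_ca_a6a11": 4.781234},
            {"pdb_id": "BBBB", "model": 1, "chain": "AB", "class": "CLASS2",
             "ca_ca_a6a11": 4.54678},
        ]
        path = write_survey(rows, tmp_path / "s.tsv")
        df = read_survey(path)
        assert len(df) == 2
        assert list(df["pdb_id"]) == ["AAAA", "BBBB"]
        # distances printed at 0.01 A precision
        assert df["ca_ca_a6a11"].tolist() == [4.78, 4.55]

    def test_deterministic_row_order(self, tmp_path):
        rows = [
            {"pdb_id": "B", "model": 1, "chain": "AB", "x": 1},
            {"pdb_id": "A", "model": 2, "chain": "AB", "x": 2},
            {"pdb_id": "A", "model": 1, "chain": "AB", "x": 3},
        ]
        p1 = write_survey(rows, tmp_path / "a.tsv")
        p2 = write_survey(list(reversed(rows)), tmp_path / "b.tsv")
        assert p1.read_text() == p2.read_text()

    def test_mismatched_schema_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_survey([{"a": 1}, {"b": 2}], tmp_path / "x.tsv")
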