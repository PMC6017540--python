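import math

import numpy as np
import pytest

from vstriage.receptor import (
    Atom,
    ChainNotFoundError,
    CleaningReport,
    ReceptorError,
    ReceptorStructure,
    clean_receptor,
    read_pdb,
    receptor_grid_bounds,
    write_pdb,
)


def _counts(structure):
    by = {"ATOM": 0, "HETATM": 0, "HOH": 0, "ion": 0}
    for a in structure.atoms:
        by[a.record_kind] += 1
        if a.residue_name == "HOH":
            by["HOH"] += 1
        if a.residue_name in ("NA", "CL"):
            by["ion"] += 1
    return by


class TestCleanReceptor:
    def test_two_chain_fixture_keeps_only_chain_a_protein(self, two_chain_pdb):
        raw = read_pdb(two_chain_pdb)
        before = _counts(raw)
        assert before["ATOM"] == 100 and before["HOH"] == 30 and before["ion"] == 2

        report = CleaningReport()
        cleaned = clean_receptor(raw, keep_chain="A", report=report)
        after = _counts(cleaned)
        assert len(cleaned) == 50
        assert after == {"ATOM": 50, "HETATM": 0, "HOH": 0, "ion": 0}
        assert cleaned.chains == {"A"}
        assert report.other_chains == 50 and report.waters == 30 and report.ions == 2

    def test_single_chain_no_hetatm_is_identity(self, two_chain_pdb):
        once = clean_receptor(read_pdb(two_chain_pdb), keep_chain="B")
        again = clean_receptor(once, keep_chain="B")
        assert again == once
        assert [a.serial for a in once.atoms] == list(range(1, len(once) + 1))

    def test_missing_chain_error_names_available_chains(self, two_chain_pdb):
        raw = read_pdb(two_chain_pdb)
        with pytest.raises(ChainNotFoundError, match=r"A, B"):
            clean_receptor(raw, keep_chain="Z")

    def test_coordinates_of_retained_atoms_unchanged(self, two_chain_pdb):
        raw = read_pdb(two_chain_pdb)
        cleaned = clean_receptor(raw, keep_chain="A")
        originals = {
            (a.chain_id, a.residue_number, a.name): (a.x, a.y, a.z)
            for a in raw.atoms
            if a.record_kind == "ATOM" and a.chain_id == "A"
        }
        for a in cleaned.atoms:
            assert (a.x, a.y, a.z) == originals[(a.chain_id, a.residue_number, a.name)]

    def test_whitelisted_cofactor_is_retained(self):
        atoms = [
            Atom("ATOM", 1, "CA", "", "ALA", "A", 1, 0.0, 0.0, 0.0),
            Atom("HETATM", 2, "ZN", "", "ZN", "A", 2, 1.0, 1.0, 1.0),
            Atom("HETATM", 3, "O", "", "HOH", "A", 3, 2.0, 2.0, 2.0),
        ]
        raw = ReceptorStructure(atoms=tuple(atoms))
        cleaned = clean_receptor(raw, keep_chain="A", het_whitelist={"ZN"})
        assert [a.residue_name for a in cleaned.atoms] == ["ALA", "ZN"]

    def test_water_only_chain_raises(self):
        raw = ReceptorStructure(
            atoms=(Atom("HETATM", 1, "O", "", "HOH", "A", 1, 0.0, 0.0, 0.0),)
        )
        with pytest.raises(ReceptorError, match="no atoms"):
            clean_receptor(raw, keep_chain="A")

    def test_alternate_locations_b_dropped(self):
        atoms = [
            Atom("ATOM", 1, "CA", "A", "ALA", "A", 1, 0.0, 0.0, 0.0),
            Atom("ATOM", 2, "CA", "B", "ALA", "A", 1, 0.5, 0.0, 0.0),
        ]
        cleaned = clean_receptor(ReceptorStructure(atoms=tuple(atoms)), keep_chain="A")
        assert len(cleaned) == 1 and cleaned.atoms[0].alt_loc == "A"


class TestGridBounds:
    def test_two_atom_closed_form(self):
        atoms = (
            Atom("ATOM", 1, "CA", "", "ALA", "A", 1, 0.0, 0.0, 0.0),
            Atom("ATOM", 2, "CA", "", "ALA", "A", 2, 10.0, 0.0, 0.0),
        )
        r = ReceptorStructure(atoms=atoms)
        box = receptor_grid_bounds(r, margin=0.0)
        assert box.centre == (5.0, 0.0, 0.0)
        assert box.edges == (10.0, 0.0, 0.0)
        box5 = receptor_grid_bounds(r, margin=5.0)
        assert box5.edges == (20.0, 10.0, 10.0)

    def test_random_cloud_containment(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-20, 20, size=(100, 3))
        atoms = tuple(
            Atom("ATOM", i + 1, "CA", "", "ALA", "A", i + 1, *map(float, p))
            for i, p in enumerate(pts)
        )
        box = receptor_grid_bounds(ReceptorStructure(atoms=atoms), margin=1.5)
        assert all(box.contains(p) for p in pts)

    @pytest.mark.parametrize("m_small,m_big", [(0.0, 2.0), (1.0, 5.0)])
    def test_margin_nesting(self, two_chain_pdb, m_small, m_big):
        r = read_pdb(two_chain_pdb)
        small = receptor_grid_bounds(r, margin=m_small)
        big = receptor_grid_bounds(r, margin=m_big)
        assert all(b <= s for b, s in zip(big.lo, small.lo))
        assert all(b >= s for b, s in zip(big.hi, small.hi))

    def test_negative_margin_rejected(self, two_chain_pdb):
        with pytest.raises(ValueError):
            receptor_grid_bounds(read_pdb(two_chain_pdb), margin=-1.0)


class TestPdbRoundTrip:
    def test_write_read_preserves_records(self, two_chain_pdb, tmp_path):
        cleaned = clean_receptor(read_pdb(two_chain_pdb), keep_chain="A")
        out = tmp_path / "clean.pdb"
        write_pdb(cleaned, out)
        reread = read_pdb(out)
        assert len(reread) == len(cleaned)
        for a, b in zip(cleaned.atoms, reread.atoms):
            assert (a.record_kind, a.serial, a.chain_id, a.residue_number) == (
                b.record_kind, b.serial, b.chain_id, b.residue_number,
            )
            assert (a.x, a.y, a.z) == (b.x, b.y, b.z)  # %8.3f round-trips exactly

    def test_default_occupancy_bfactor_written(self, tmp_path):
        atoms = (Atom("ATOM", 1, "CA", "", "ALA", "A", 1, 1.0, 2.0, 3.0),)
        out = tmp_path / "one.pdb"
        write_pdb(ReceptorStructure(atoms=atoms), out)
        line = out.read_text().splitlines()[0]
        assert line[54:60] == "  1.00" and line[60:66] == "  0.00"

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ReceptorError):
            ReceptorStructure(
                atoms=(Atom("ATOM", 1, "CA", "", "ALA", "A", 1, math.nan, 0.0, 0.0),)
            )
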