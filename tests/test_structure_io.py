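"""Parsing, template bonds and the 23-dim atom featurization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gatedock import (
    ContractError,
    PDBParseError,
    apply_rigid,
    atom_features,
    infer_bonds,
    parse_pdb,
    write_pdb,
)
from gatedock.structure_io import FEATURE_LENGTH

from conftest import atom_line, make_pdb_text


def _write(tmp_path, name, lines):
    path = tmp_path / name
    path.write_text(make_pdb_text(lines))
    return path


@pytest.fixture()
def two_chain_pdb(tmp_path):
    """Chain A: 2 glycines; chain B: 1 alanine, 8 A away."""
    lines = []
    serial = 0
    for i, base in enumerate([0.0, 3.4]):
        for name, (x, y, z) in [("N", (0, 0, 0)), ("CA", (1.46, 0, 0)),
                                ("C", (2.19, 1.33, 0)), ("O", (1.79, 2.49, 0))]:
            serial += 1
            lines.append(atom_line(serial, name, "GLY", "A", i + 1,
                                   base + x, y, z))
    for name, (x, y, z) in [("N", (0, 0, 8)), ("CA", (1.46, 0, 8)),
                            ("C", (2.19, 1.33, 8)), ("O", (1.79, 2.49, 8)),
                            ("CB", (1.06, -0.8, 9.2))]:
        serial += 1
        lines.append(atom_line(serial, name, "ALA", "B", 1, x, y, z))
    return _write(tmp_path, "two_chain.pdb", lines)


class TestParse:
    def test_counts_and_partition(self, two_chain_pdb):
        s = parse_pdb(two_chain_pdb, {"A"}, {"B"})
        assert len(s.receptor) == 2
        assert len(s.ligand) == 1
        assert len(s.ligand[0].atoms) == 5

    def test_empty_ligand_chain_is_an_error(self, tmp_path):
        path = _write(tmp_path, "one.pdb",
                      [atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0)])
        with pytest.raises(PDBParseError, match="no atoms in ligand chains"):
            parse_pdb(path, {"A"}, {"B"})

    def test_altloc_keeps_first_conformer(self, tmp_path):
        lines = [
            atom_line(1, "N", "GLY", "A", 1, 0, 0, 0),
            atom_line(2, "CA", "GLY", "A", 1, 1.0, 0, 0, altloc="A"),
            atom_line(3, "CA", "GLY", "A", 1, 9.0, 0, 0, altloc="B"),
            atom_line(4, "CA", "ALA", "B", 1, 0, 0, 5),
        ]
        s = parse_pdb(_write(tmp_path, "alt.pdb", lines), {"A"}, {"B"})
        cas = [a for a in s.receptor[0].atoms if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].coords[0] == pytest.approx(1.0)

    def test_hetatm_and_waters_skipped(self, tmp_path):
        lines = [
            atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            atom_line(2, "O", "HOH", "A", 2, 3, 3, 3, record="HETATM"),
            atom_line(3, "CA", "ALA", "B", 1, 0, 0, 5),
        ]
        s = parse_pdb(_write(tmp_path, "het.pdb", lines), {"A"}, {"B"})
        assert len(s.receptor) == 1

    def test_malformed_coordinates_name_the_line(self, tmp_path):
        bad = atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0)[:30] + "  badnum" + " " * 16
        path = _write(tmp_path, "bad.pdb",
                      [atom_line(1, "CA", "ALA", "B", 1, 0, 0, 5), bad])
        with pytest.raises(PDBParseError, match=r":2: malformed coordinate"):
            parse_pdb(path, {"A"}, {"B"})

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_pdb(tmp_path / "nope.pdb", {"A"}, {"B"})

    def test_overlapping_chain_sets_rejected(self, two_chain_pdb):
        with pytest.raises(ContractError):
            parse_pdb(two_chain_pdb, {"A"}, {"A"})


class TestBonds:
    def test_single_glycine_template_bonds(self, two_chain_pdb):
        s = parse_pdb(two_chain_pdb, {"A"}, {"B"})
        graph = infer_bonds(s.receptor[:1])
        assert len(graph) == 3  # N-CA, CA-C, C-O

    def test_peptide_bond_added_within_cutoff(self, two_chain_pdb):
        s = parse_pdb(two_chain_pdb, {"A"}, {"B"})
        graph = infer_bonds(s.receptor)
        c = s.receptor[0].get("C")
        n = s.receptor[1].get("N")
        assert np.linalg.norm(c.coords - n.coords) < 2.0
        assert graph.has(c.atom_id, n.atom_id)

    def test_chain_break_leaves_no_peptide_bond(self, tmp_path):
        lines = []
        serial = 0
        for i, base in enumerate([0.0, 6.0]):  # C-N distance ~5 A
            for name, (x, y, z) in [("N", (0, 0, 0)), ("CA", (1.46, 0, 0)),
                                    ("C", (2.19, 1.33, 0)), ("O", (1.79, 2.49, 0))]:
                serial += 1
                lines.append(atom_line(serial, name, "ALA", "A", i + 1,
                                       base + x, y, z))
        lines.append(atom_line(99, "CA", "GLY", "B", 1, 0, 0, 5))
        s = parse_pdb(_write(tmp_path, "break.pdb", lines), {"A"}, {"B"})
        graph = infer_bonds(s.receptor)
        c = s.receptor[0].get("C")
        n = s.receptor[1].get("N")
        assert not graph.has(c.atom_id, n.atom_id)

    def test_bond_graph_invariant_under_rigid_motion(self, toy_native):
        graph = infer_bonds(toy_native.receptor)
        R = Rotation.from_rotvec([0.5, -1.0, 0.2]).as_matrix()
        moved = apply_rigid(toy_native, R, np.array([10.0, -4.0, 2.0]))
        assert infer_bonds(moved.receptor).bonds == graph.bonds


class TestFeatures:
    def test_every_heavy_atom_gets_23_dims_with_unit_blocks(self, toy_native):
        graph = infer_bonds(toy_native.receptor)
        for res in toy_native.receptor:
            for atom in res.heavy_atoms():
                v = atom_features(atom, graph, res)
                assert v.shape == (FEATURE_LENGTH,)
                blocks = np.split(v, [5, 11, 16, 22])
                for block in blocks[:4]:
                    assert block.sum() == 1.0
                assert blocks[4][0] in (0.0, 1.0)
                assert v.sum() == 4.0 + blocks[4][0]

    def test_glycine_ca_feature_blocks(self, two_chain_pdb):
        s = parse_pdb(two_chain_pdb, {"A"}, {"B"})
        graph = infer_bonds(s.receptor)
        res = s.receptor[0]
        v = atom_features(res.get("CA"), graph, res)
        assert list(v[:5]) == [1, 0, 0, 0, 0]  # carbon
        assert v[5 + 2] == 1  # degree 2 (N, C)
        assert v[11 + 2] == 1  # two template hydrogens
        assert v[22] == 0  # not aromatic

    def test_tryptophan_ring_atom_is_aromatic(self, tmp_path):
        # minimal TRP with a ring atom; coordinates are irrelevant to the flag
        names = ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1",
                 "CE2", "CE3", "CZ2", "CZ3", "CH2"]
        lines = [atom_line(i + 1, n, "TRP", "A", 1, i * 1.0, 0, 0)
                 for i, n in enumerate(names)]
        lines.append(atom_line(99, "CA", "GLY", "B", 1, 0, 0, 5))
        s = parse_pdb(_write(tmp_path, "trp.pdb", lines), {"A"}, {"B"})
        res = s.receptor[0]
        graph = infer_bonds(s.receptor)
        v = atom_features(res.get("CZ2"), graph, res)
        assert v[22] == 1.0

    def test_hydrogen_atom_rejected(self, two_chain_pdb, tmp_path):
        lines = [
            atom_line(1, "N", "GLY", "A", 1, 0, 0, 0),
            atom_line(2, "H", "GLY", "A", 1, 0.5, 0.5, 0, element="H"),
            atom_line(3, "CA", "ALA", "B", 1, 0, 0, 5),
        ]
        s = parse_pdb(_write(tmp_path, "h.pdb", lines), {"A"}, {"B"})
        res = s.receptor[0]
        h = res.get("H")
        assert not h.is_heavy
        with pytest.raises(ContractError):
            atom_features(h, infer_bonds(s.receptor), res)


class TestWrite:
    def test_round_trip_preserves_fields(self, toy_native, tmp_path):
        path = tmp_path / "native.pdb"
        write_pdb(toy_native, path)
        back = parse_pdb(path, {"A"}, {"B"})
        orig_atoms = [a for r in toy_native.receptor + toy_native.ligand
                      for a in r.atoms]
        back_atoms = [a for r in back.receptor + back.ligand for a in r.atoms]
        assert len(back_atoms) == len(orig_atoms)
        for a, b in zip(orig_atoms, back_atoms):
            assert a.name == b.name
            assert a.residue_key == b.residue_key
            assert np.allclose(a.coords, b.coords, atol=5.1e-4)

    def test_parse_write_parse_idempotent(self, toy_native, tmp_path):
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_pdb(toy_native, p1)
        s1 = parse_pdb(p1, {"A"}, {"B"})
        write_pdb(s1, p2)
        assert p1.read_text() == p2.read_text()

    def test_empty_subunit_rejected_before_write(self, toy_native, tmp_path):
        from gatedock import Structure

        broken = Structure(toy_native.receptor, [], "x")
        with pytest.raises(ContractError):
            write_pdb(broken, tmp_path / "x.pdb")
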