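"""Residue chemistry templates for the 20 standard amino acids.

The featurizer and bond inference never run chemical perception on the
input coordinates: the covalent topology, hydrogen counts and aromatic
ring membership of every standard residue are fixed chemistry, so they
are tabulated here once.  Each entry lists

``bonds``      heavy-atom bonds within the residue (PDB atom names);
``hydrogens``  number of hydrogens attached to each heavy atom at
               neutral pH, mid-chain (terminal extras are ignored);
``aromatic``   atom names belonging to an aromatic ring (His, Phe,
               Tyr, Trp side chains).

The backbone (N-CA, CA-C, C-O, plus C-OXT when a terminal oxygen is
present) is shared by all entries and added programmatically.  The
peptide link C(i)-N(i+1) is a between-residue bond and is handled by
bond inference, not by the table.
"""

from __future__ import annotations

TEMPLATE_VERSION = "1.0"

#: total bonding valence used for the implicit-valence feature
ELEMENT_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}

_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O")]
_BACKBONE_H = {"N": 1, "CA": 1, "C": 0, "O": 0, "OXT": 1}

# side-chain definitions: (bonds, hydrogens, aromatic atoms)
_SIDE_CHAINS: dict[str, tuple[list[tuple[str, str]], dict[str, int], set[str]]] = {
    "ALA": ([("CA", "CB")], {"CB": 3}, set()),
    "ARG": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
         ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
        {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "CZ": 0, "NH1": 2, "NH2": 2},
        set(),
    ),
    "ASN": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
        {"CB": 2, "CG": 0, "OD1": 0, "ND2": 2},
        set(),
    ),
    "ASP": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
        {"CB": 2, "CG": 0, "OD1": 0, "OD2": 0},
        set(),
    ),
    "CYS": ([("CA", "CB"), ("CB", "SG")], {"CB": 2, "SG": 1}, set()),
    "GLN": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
        {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "NE2": 2},
        set(),
    ),
    "GLU": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
        {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "OE2": 0},
        set(),
    ),
    "GLY": ([], {}, set()),
    "HIS": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
         ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
        {"CB": 2, "CG": 0, "ND1": 0, "CD2": 1, "CE1": 1, "NE2": 1},
        {"CG", "ND1", "CD2", "CE1", "NE2"},
    ),
    "ILE": (
        [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
        {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
        set(),
    ),
    "LEU": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
        {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
        set(),
    ),
    "LYS": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
        {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
        set(),
    ),
    "MET": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
        {"CB": 2, "CG": 2, "SD": 0, "CE": 3},
        set(),
    ),
    "PHE": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
         ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
        {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
        {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    ),
    "PRO": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
        {"CB": 2, "CG": 2, "CD": 2, "N": 0},
        set(),
    ),
    "SER": ([("CA", "CB"), ("CB", "OG")], {"CB": 2, "OG": 1}, set()),
    "THR": (
        [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
        {"CB": 1, "OG1": 1, "CG2": 3},
        set(),
    ),
    "TRP": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
         ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
         ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")],
        {"CB": 2, "CG": 0, "CD1": 1, "NE1": 1, "CD2": 0, "CE2": 0,
         "CE3": 1, "CZ3": 1, "CH2": 1, "CZ2": 1},
        {"CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"},
    ),
    "TYR": (
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
         ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
         ("CZ", "OH")],
        {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1,
         "CZ": 0, "OH": 1},
        {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    ),
    "VAL": (
        [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
        {"CB": 1, "CG1": 3, "CG2": 3},
        set(),
    ),
}

STANDARD_RESIDUES = frozenset(_SIDE_CHAINS)


def residue_bonds(resname: str) -> list[tuple[str, str]] | None:
    """Heavy-atom bond list for a standard residue, backbone included.

    Returns None for residues not in the template table.
    """
    sc = _SIDE_CHAINS.get(resname)
    if sc is None:
        return None
    bonds = list(_BACKBONE_BONDS) + list(sc[0])
    bonds.append(("C", "OXT"))  # applied only if OXT is present
    return bonds


def hydrogen_count(resname: str, atom_name: str) -> int:
    """Template hydrogens attached to a heavy atom (0 if unknown)."""
    sc = _SIDE_CHAINS.get(resname)
    if sc is None:
        return 0
    if resname == "PRO" and atom_name == "N":
        return 0
    if resname == "GLY" and atom_name == "CA":
        return 2
    if atom_name in sc[1]:
        return sc[1][atom_name]
    return _BACKBONE_H.get(atom_name, 0)


def is_aromatic(resname: str, atom_name: str) -> bool:
    sc = _SIDE_CHAINS.get(resname)
    return sc is not None and atom_name in sc[2]
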