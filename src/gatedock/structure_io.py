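"""PDB parsing, template-based bond inference and atom featurization.

A docking model is a two-chain-set complex: a *receptor* and a
*ligand* subunit, each one or more chains of a standard PDB file.
This module turns ATOM records into a :class:`Structure`, derives the
covalent topology of each subunit from the residue templates in
:mod:`gatedock.templates`, and computes the 23-dimensional binary
feature vector of every heavy atom:

    atom type one-hot (C, N, O, S, H)          5
    heavy-atom degree one-hot (0..5)           6
    attached hydrogens one-hot (0..4)          5
    implicit valence one-hot (0..5)            6
    aromatic flag                              1

Hydrogens are retained by the parser (flagged non-heavy) but never
become graph nodes; attached-hydrogen counts come from the residue
templates, not from file content, because docking decoys are usually
not protonated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .templates import (
    ELEMENT_VALENCE,
    hydrogen_count,
    is_aromatic,
    residue_bonds,
)

logger = logging.getLogger(__name__)

FEATURE_LENGTH = 23
_TYPE_ORDER = ("C", "N", "O", "S", "H")
PEPTIDE_BOND_CUTOFF = 2.0  # Angstrom, C(i)-N(i+1)
FALLBACK_BOND_CUTOFF = 1.9  # Angstrom, non-template residues

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Raised for malformed or contract-violating PDB input."""


class ContractError(ValueError):
    """Raised when an operation precondition is violated."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)
AtomId = tuple[ResidueKey, str]  # (residue key, atom name)


@dataclass
class Atom:
    serial: int
    name: str
    element: str  # one of C, N, O, S, H, other
    coords: np.ndarray  # shape (3,), Angstrom
    residue_key: ResidueKey
    is_heavy: bool

    @property
    def atom_id(self) -> AtomId:
        return (self.residue_key, self.name)


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def get(self, atom_name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)


@dataclass
class Structure:
    receptor: list[Residue]
    ligand: list[Residue]
    source_path: str = ""

    def subunit(self, which: str) -> list[Residue]:
        if which == "receptor":
            return self.receptor
        if which == "ligand":
            return self.ligand
        raise ValueError(f"unknown subunit {which!r}")

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.receptor + self.ligand}

    def copy(self) -> "Structure":
        def _copy_res(res: Residue) -> Residue:
            return Residue(
                res.key,
                res.name,
                [Atom(a.serial, a.name, a.element, a.coords.copy(),
                      a.residue_key, a.is_heavy) for a in res.atoms],
            )

        return Structure(
            [_copy_res(r) for r in self.receptor],
            [_copy_res(r) for r in self.ligand],
            self.source_path,
        )


class BondGraph:
    """Covalent bonds of one subunit as unordered heavy-atom id pairs."""

    def __init__(self) -> None:
        self._adj: dict[AtomId, set[AtomId]] = {}

    def add(self, a: AtomId, b: AtomId) -> None:
        if a == b:
            return
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    def neighbors(self, a: AtomId) -> set[AtomId]:
        return self._adj.get(a, set())

    def degree(self, a: AtomId) -> int:
        return len(self._adj.get(a, ()))

    def has(self, a: AtomId, b: AtomId) -> bool:
        return b in self._adj.get(a, ())

    @property
    def bonds(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, nbrs in self._adj.items() for b in nbrs}

    def __len__(self) -> int:
        return len(self.bonds)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _element_from_line(line: str) -> str:
    elem = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not elem:
        name = line[12:16]
        stripped = name.strip().lstrip("0123456789")
        elem = stripped[:1].upper()
        # four-character names starting in column 13 ("1HG1") are hydrogens
        if name[0].isdigit() and stripped[:1].upper() in ("H", "D"):
            elem = "H"
    if elem in ("D", "T"):
        elem = "H"
    if elem in _TYPE_ORDER:
        return elem
    return "other"


def parse_pdb(path, receptor_chains, ligand_chains) -> Structure:
    """Parse a two-subunit complex model from a PDB file.

    ATOM records only (HETATM and waters are skipped); alternate
    locations resolve to the first-listed conformer; only the first
    MODEL of a multi-model file is read.  Chains not listed in either
    set are ignored.
    """
    path = Path(path)
    receptor_chains = set(receptor_chains)
    ligand_chains = set(ligand_chains)
    if not receptor_chains or not ligand_chains:
        raise ContractError("receptor and ligand chain sets must be non-empty")
    if receptor_chains & ligand_chains:
        raise ContractError(
            f"chain sets overlap: {sorted(receptor_chains & ligand_chains)}")
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")

    wanted = receptor_chains | ligand_chains
    residues: dict[ResidueKey, Residue] = {}
    order: list[ResidueKey] = []
    seen_atoms: set[AtomId] = set()
    in_model = 0

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6]
            if rec.startswith("MODEL"):
                in_model += 1
                if in_model > 1:
                    break
                continue
            if rec.startswith("ENDMDL"):
                break
            if not rec.startswith("ATOM"):
                continue
            line = raw.rstrip("\n")
            if len(line) < 54:
                raise PDBParseError(f"{path}:{lineno}: truncated ATOM record")
            chain = line[21]
            if chain not in wanted:
                continue
            resname = line[17:20].strip()
            if resname in _WATER_NAMES:
                continue
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = 0
            name = line[12:16].strip()
            try:
                resnum = int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(
                    f"{path}:{lineno}: malformed residue number") from exc
            icode = line[26].strip()
            try:
                coords = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except ValueError as exc:
                raise PDBParseError(
                    f"{path}:{lineno}: malformed coordinate fields") from exc
            if not np.all(np.isfinite(coords)):
                raise PDBParseError(f"{path}:{lineno}: non-finite coordinates")

            key: ResidueKey = (chain, resnum, icode)
            atom_id: AtomId = (key, name)
            if atom_id in seen_atoms:  # altloc duplicates: first conformer wins
                continue
            seen_atoms.add(atom_id)

            element = _element_from_line(line)
            atom = Atom(serial, name, element, coords, key, element != "H")
            if key not in residues:
                residues[key] = Residue(key, resname)
                order.append(key)
            residues[key].atoms.append(atom)

    receptor = [residues[k] for k in order if k[0] in receptor_chains]
    ligand = [residues[k] for k in order if k[0] in ligand_chains]
    if not receptor:
        raise PDBParseError(f"no atoms in receptor chains {sorted(receptor_chains)}")
    if not ligand:
        raise PDBParseError(f"no atoms in ligand chains {sorted(ligand_chains)}")
    return Structure(receptor, ligand, str(path))


def write_pdb(structure: Structure, path) -> None:
    """Write a structure as fixed-column ATOM records (TER between chains)."""
    if not structure.receptor or not structure.ligand:
        raise ContractError("cannot write a structure with an empty subunit")
    serial = 0
    lines: list[str] = []
    for subunit in (structure.receptor, structure.ligand):
        last_chain = None
        for res in subunit:
            chain, resnum, icode = res.key
            if last_chain is not None and chain != last_chain:
                lines.append("TER")
            last_chain = chain
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # element-aligned name field: 1-3 char names start at col 14
                fname = f" {name:<3s}" if len(name) < 4 else name
                elem = atom.element if atom.element != "other" else ""
                lines.append(
                    f"ATOM  {serial:5d} {fname}{'':1s}{res.name:>3s} {chain}"
                    f"{resnum:4d}{icode or ' '}   "
                    f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {elem:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bonds
# ---------------------------------------------------------------------------

def infer_bonds(chain: list[Residue]) -> BondGraph:
    """Covalent bonds of one subunit.

    Intra-residue bonds come from the residue template table; the
    peptide bond C(i)-N(i+1) is added for consecutive residues whose
    C-N distance is below 2.0 A.  Residues without a template fall
    back to a distance rule (heavy-atom pairs closer than 1.9 A).
    """
    graph = BondGraph()
    for res in chain:
        template = residue_bonds(res.name)
        heavy = res.heavy_atoms()
        present = {a.name: a for a in heavy}
        if template is not None:
            for a_name, b_name in template:
                if a_name in present and b_name in present:
                    graph.add(present[a_name].atom_id, present[b_name].atom_id)
        else:
            logger.warning(
                "residue %s %s has no template; using %.1f A distance rule",
                res.name, res.key, FALLBACK_BOND_CUTOFF)
            for i in range(len(heavy)):
                for j in range(i + 1, len(heavy)):
                    d = np.linalg.norm(heavy[i].coords - heavy[j].coords)
                    if d < FALLBACK_BOND_CUTOFF:
                        graph.add(heavy[i].atom_id, heavy[j].atom_id)
    for prev, nxt in zip(chain, chain[1:]):
        c = prev.get("C")
        n = nxt.get("N")
        if c is not None and n is not None:
            if np.linalg.norm(c.coords - n.coords) < PEPTIDE_BOND_CUTOFF:
                graph.add(c.atom_id, n.atom_id)
    return graph


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def _one_hot(index: int, length: int) -> np.ndarray:
    v = np.zeros(length)
    v[index] = 1.0
    return v


def atom_features(atom: Atom, bond_graph: BondGraph,
                  residue_context: Residue) -> np.ndarray:
    """23-dim binary feature vector of a heavy atom (see module docstring)."""
    if not atom.is_heavy:
        raise ContractError(
            f"atom_features is defined for heavy atoms only, got {atom.name}")
    element = atom.element
    if element not in ("C", "N", "O", "S"):
        logger.warning("atom %s has element %r; typing as C", atom.name, element)
        element = "C"
    type_block = _one_hot(_TYPE_ORDER.index(element), 5)

    degree = min(bond_graph.degree(atom.atom_id), 5)
    degree_block = _one_hot(degree, 6)

    n_h = min(hydrogen_count(residue_context.name, atom.name), 4)
    h_block = _one_hot(n_h, 5)

    valence = ELEMENT_VALENCE.get(element, 4)
    implicit = min(max(valence - bond_graph.degree(atom.atom_id), 0), 5)
    valence_block = _one_hot(implicit, 6)

    aromatic = np.array([1.0 if is_aromatic(residue_context.name, atom.name) else 0.0])
    return np.concatenate([type_block, degree_block, h_block, valence_block, aromatic])


# ---------------------------------------------------------------------------
# rigid-body helpers (used by decoy generation and metrics)
# ---------------------------------------------------------------------------

def apply_rigid(structure: Structure, rotation: np.ndarray,
                translation: np.ndarray, which: str = "both") -> Structure:
    """Return a copy with ``x -> R x + t`` applied to one or both subunits."""
    out = structure.copy()
    subunits = {"receptor": [out.receptor], "ligand": [out.ligand],
                "both": [out.receptor, out.ligand]}[which]
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    for residues in subunits:
        for res in residues:
            for atom in res.atoms:
                atom.coords = R @ atom.coords + t
    return out
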