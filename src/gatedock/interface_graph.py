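"""Interface extraction and the two-graph representation of a decoy.

The interface of a complex model is the set of residues of either
subunit whose minimum heavy-atom distance to any residue of the other
subunit is at most a cutoff (10 A by default).  Over the heavy atoms
of those residues two adjacency matrices are defined:

``A1``  covalent bonds within each subunit, plus the unit diagonal;
``A2``  equal to A1 within a subunit; across subunits, atom pairs
        closer than a distance cutoff get a Gaussian weight
        exp(-(d - mu)^2 / sigma) with learnable scalars mu, sigma.

Because mu and sigma are trained, the graph pair stores the raw
cross-subunit distance matrix and A2 is recomputed from it on every
forward pass; :meth:`InterfaceGraphPair.a2` provides the numpy version
for inspection and serialization-free use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import (
    Atom,
    BondGraph,
    ContractError,
    ResidueKey,
    Structure,
    atom_features,
    infer_bonds,
)

logger = logging.getLogger(__name__)

INTERFACE_RESIDUE_CUTOFF = 10.0  # A, residue selection
CROSS_EDGE_CUTOFF = 10.0  # A, non-covalent atom pair edges
SIGMA_FLOOR = 1e-6


class NoInterfaceError(ValueError):
    """No residue pair of the two subunits lies within the cutoff."""


@dataclass
class InterfaceSelection:
    receptor_residues: list[ResidueKey]
    ligand_residues: list[ResidueKey]
    cutoff: float = INTERFACE_RESIDUE_CUTOFF


@dataclass
class EdgeParams:
    """Learnable Gaussian edge-weight parameters (shared by all cross edges)."""

    mu: float = 0.0
    sigma: float = 1.0

    def clamped_sigma(self) -> float:
        if self.sigma < SIGMA_FLOOR:
            logger.warning("sigma=%g clamped to %g", self.sigma, SIGMA_FLOOR)
            return SIGMA_FLOOR
        return self.sigma


@dataclass
class InterfaceGraphPair:
    """Node features plus the covalent and cross-molecular adjacencies.

    Nodes are the heavy atoms of the selected interface residues,
    receptor block first, then ligand block, each in file order.
    ``cross_dist`` holds cross-subunit atom distances where they are
    at most the cross-edge cutoff and +inf elsewhere (including all
    within-subunit entries).
    """

    atoms: list[Atom]
    features: np.ndarray  # (N, 23)
    a1: np.ndarray  # (N, N) binary, unit diagonal
    cross_dist: np.ndarray  # (N, N), +inf off-support
    molecule_of: np.ndarray  # (N,) 0 = receptor, 1 = ligand
    cutoff: float = CROSS_EDGE_CUTOFF
    edge_params: EdgeParams = field(default_factory=EdgeParams)

    @property
    def n_nodes(self) -> int:
        return len(self.atoms)

    def cross_mask(self) -> np.ndarray:
        return np.isfinite(self.cross_dist)

    def a2(self, mu: float | None = None, sigma: float | None = None) -> np.ndarray:
        """A2 for given (mu, sigma); defaults to the stored edge params."""
        mu = self.edge_params.mu if mu is None else mu
        sigma = self.edge_params.sigma if sigma is None else sigma
        sigma = max(sigma, SIGMA_FLOOR)
        mask = self.cross_mask()
        weights = np.zeros_like(self.a1)
        d = self.cross_dist[mask]
        weights[mask] = np.exp(-((d - mu) ** 2) / sigma)
        # supports are disjoint: A1 is zero on every cross-subunit entry
        return self.a1 + weights


def extract_interface(structure: Structure,
                      cutoff: float = INTERFACE_RESIDUE_CUTOFF) -> InterfaceSelection:
    """Select interface residues of both subunits symmetrically.

    A residue is selected iff its minimum heavy-atom distance to any
    residue of the other subunit is <= cutoff.
    """
    rec_coords = [r.heavy_coords() for r in structure.receptor]
    lig_coords = [r.heavy_coords() for r in structure.ligand]
    if not rec_coords or not lig_coords:
        raise ContractError("structure must have both subunits")

    rec_all = np.concatenate([c for c in rec_coords if len(c)])
    lig_all = np.concatenate([c for c in lig_coords if len(c)])
    dmat = cdist(rec_all, lig_all)

    rec_idx = np.repeat(np.arange(len(rec_coords)),
                        [len(c) for c in rec_coords])
    lig_idx = np.repeat(np.arange(len(lig_coords)),
                        [len(c) for c in lig_coords])

    rec_min = np.full(len(rec_coords), np.inf)
    lig_min = np.full(len(lig_coords), np.inf)
    row_min = dmat.min(axis=1)
    col_min = dmat.min(axis=0)
    np.minimum.at(rec_min, rec_idx, row_min)
    np.minimum.at(lig_min, lig_idx, col_min)

    rec_sel = [structure.receptor[i].key for i in range(len(rec_coords))
               if rec_min[i] <= cutoff]
    lig_sel = [structure.ligand[i].key for i in range(len(lig_coords))
               if lig_min[i] <= cutoff]
    if not rec_sel or not lig_sel:
        raise NoInterfaceError(
            f"no interface: no residue pair within {cutoff} A")
    return InterfaceSelection(rec_sel, lig_sel, cutoff)


def build_graph_pair(structure: Structure, selection: InterfaceSelection,
                     edge_params: EdgeParams | None = None,
                     cross_cutoff: float = CROSS_EDGE_CUTOFF) -> InterfaceGraphPair:
    """Build node features, A1 and the cross-distance support for A2."""
    if edge_params is None:
        edge_params = EdgeParams()
    if not selection.receptor_residues or not selection.ligand_residues:
        raise ContractError("selection must be non-empty on both sides")
    edge_params.sigma = edge_params.clamped_sigma()

    rec_keys = set(selection.receptor_residues)
    lig_keys = set(selection.ligand_residues)

    rec_bonds = infer_bonds(structure.receptor)
    lig_bonds = infer_bonds(structure.ligand)

    atoms: list[Atom] = []
    feats: list[np.ndarray] = []
    molecule: list[int] = []

    def _collect(residues, keys, bonds: BondGraph, mol: int):
        for res in residues:
            if res.key not in keys:
                continue
            for atom in res.heavy_atoms():
                atoms.append(atom)
                feats.append(atom_features(atom, bonds, res))
                molecule.append(mol)

    _collect(structure.receptor, rec_keys, rec_bonds, 0)
    _collect(structure.ligand, lig_keys, lig_bonds, 1)

    n = len(atoms)
    index_of = {a.atom_id: i for i, a in enumerate(atoms)}
    a1 = np.eye(n)
    for bonds in (rec_bonds, lig_bonds):
        for pair in bonds.bonds:
            a, b = tuple(pair)
            ia, ib = index_of.get(a), index_of.get(b)
            if ia is not None and ib is not None:
                a1[ia, ib] = a1[ib, ia] = 1.0

    coords = np.array([a.coords for a in atoms])
    mol = np.array(molecule)
    dmat = cdist(coords, coords)
    cross = mol[:, None] != mol[None, :]
    cross_dist = np.where(cross & (dmat <= cross_cutoff), dmat, np.inf)

    return InterfaceGraphPair(
        atoms=atoms,
        features=np.array(feats),
        a1=a1,
        cross_dist=cross_dist,
        molecule_of=mol,
        cutoff=cross_cutoff,
        edge_params=edge_params,
    )


def build_graph(structure: Structure,
                cutoff: float = INTERFACE_RESIDUE_CUTOFF,
                cross_cutoff: float = CROSS_EDGE_CUTOFF,
                edge_params: EdgeParams | None = None) -> InterfaceGraphPair:
    """extract_interface + build_graph_pair in one call."""
    selection = extract_interface(structure, cutoff)
    return build_graph_pair(structure, selection, edge_params, cross_cutoff)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def serialize_graph(pair: InterfaceGraphPair, path) -> None:
    """Lossless archive of a graph pair (numpy .npz, documented keys).

    Keys: features, a1, cross_dist, molecule_of, cutoff, mu, sigma,
    atom_table (chain, resnum, icode, atom name, element, serial,
    x, y, z per node) and a format version.
    """
    if pair.n_nodes == 0:
        raise ContractError("refusing to serialize an empty graph")
    atom_table = np.array(
        [(a.residue_key[0], str(a.residue_key[1]), a.residue_key[2], a.name,
          a.element, str(a.serial), repr(float(a.coords[0])),
          repr(float(a.coords[1])), repr(float(a.coords[2])))
         for a in pair.atoms])
    np.savez(
        path,
        version=np.array([_FORMAT_VERSION]),
        features=pair.features,
        a1=pair.a1,
        cross_dist=pair.cross_dist,
        molecule_of=pair.molecule_of,
        cutoff=np.array([pair.cutoff]),
        mu=np.array([pair.edge_params.mu]),
        sigma=np.array([pair.edge_params.sigma]),
        atom_table=atom_table,
    )


def deserialize_graph(path) -> InterfaceGraphPair:
    with np.load(path, allow_pickle=False) as z:
        version = int(z["version"][0])
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported graph format version {version}")
        atoms = []
        for row in z["atom_table"]:
            chain, resnum, icode, name, element, serial, x, y, z3 = row
            key = (str(chain), int(resnum), str(icode))
            atoms.append(Atom(int(serial), str(name), str(element),
                              np.array([float(x), float(y), float(z3)]),
                              key, str(element) != "H"))
        return InterfaceGraphPair(
            atoms=atoms,
            features=z["features"],
            a1=z["a1"],
            cross_dist=z["cross_dist"],
            molecule_of=z["molecule_of"],
            cutoff=float(z["cutoff"][0]),
            edge_params=EdgeParams(float(z["mu"][0]), float(z["sigma"][0])),
        )
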