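"""CAPRI-style quality metrics of a docking model against its native.

Three measures, computed on residue correspondences established by
(chain id, residue number, insertion code):

iRMSD   Calpha RMSD over the native-defined interface residues
        (native interface = residues within 10 A min heavy-atom
        distance of the partner subunit), after least-squares
        superposition of exactly those Calpha atoms;
lRMSD   Calpha RMSD of the ligand subunit after superposing the
        receptors only (no further fitting of the ligand);
fnat    fraction of native cross-subunit residue contacts (any
        heavy-atom pair within 5 A) preserved by the decoy.

The (fnat, lRMSD, iRMSD) triple maps to the standard CAPRI quality
ladder incorrect < acceptable < medium < high; the threshold table is
data (``CAPRI_THRESHOLDS``) so alternative schemes can be tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.spatial.distance import cdist

from .interface_graph import INTERFACE_RESIDUE_CUTOFF
from .structure_io import ContractError, Residue, ResidueKey, Structure

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 5.0  # A, heavy-atom residue contacts for fnat


class QualityClass(IntEnum):
    incorrect = 0
    acceptable = 1
    medium = 2
    high = 3


@dataclass
class CapriMetrics:
    irmsd: float
    lrmsd: float
    fnat: float

    def __post_init__(self):
        if self.irmsd < 0 or self.lrmsd < 0 or not (0 <= self.fnat <= 1):
            raise ValueError(f"invalid metrics: {self}")


#: (class, min fnat, max lrmsd, max irmsd) evaluated top-down;
#: the RMSD conditions are an OR (either suffices).
CAPRI_THRESHOLDS: list[tuple[QualityClass, float, float, float]] = [
    (QualityClass.high, 0.5, 1.0, 1.0),
    (QualityClass.medium, 0.3, 5.0, 2.0),
    (QualityClass.acceptable, 0.1, 10.0, 4.0),
]


def classify_quality(m: CapriMetrics,
                     thresholds=None) -> QualityClass:
    """Map an (iRMSD, lRMSD, fnat) triple to its CAPRI quality class."""
    for cls, min_fnat, max_lrmsd, max_irmsd in (thresholds or CAPRI_THRESHOLDS):
        if m.fnat >= min_fnat and (m.lrmsd <= max_lrmsd or m.irmsd <= max_irmsd):
            return cls
    return QualityClass.incorrect


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Optimal rigid superposition of P onto Q (correspondence by index).

    Returns ``(rotation, translation, rmsd)`` minimizing
    ``||R P_i + t - Q_i||`` with a proper rotation (det = +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ContractError(f"point sets must match as (M, 3), got {P.shape}, {Q.shape}")
    if len(P) < 3:
        raise ContractError(f"need at least 3 points, got {len(P)}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S = np.diag([1.0, 1.0, d])
    R = Vt.T @ S @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# interface / correspondence helpers
# ---------------------------------------------------------------------------

def native_interface_residues(native: Structure,
                              cutoff: float = INTERFACE_RESIDUE_CUTOFF
                              ) -> set[ResidueKey]:
    """Residue keys (both subunits) of the native interface."""
    from .interface_graph import extract_interface

    sel = extract_interface(native, cutoff)
    return set(sel.receptor_residues) | set(sel.ligand_residues)


def _matched_residue(decoy_map: dict[ResidueKey, Residue],
                     key: ResidueKey) -> Residue:
    res = decoy_map.get(key)
    if res is None:
        raise ContractError(f"unmatched residue {key} in decoy")
    return res


def _ca_pairs(native_residues: list[Residue],
              decoy_map: dict[ResidueKey, Residue]):
    nat, dec = [], []
    for res in native_residues:
        ca_n = res.get("CA")
        d_res = _matched_residue(decoy_map, res.key)
        ca_d = d_res.get("CA")
        if ca_n is None or ca_d is None:
            logger.warning("residue %s lacks CA; dropped from RMSD set", res.key)
            continue
        nat.append(ca_n.coords)
        dec.append(ca_d.coords)
    return np.array(dec), np.array(nat)


def irmsd(decoy: Structure, native: Structure,
          cutoff: float = INTERFACE_RESIDUE_CUTOFF) -> float:
    """Interface Calpha RMSD after superposing the interface Calphas."""
    keys = native_interface_residues(native, cutoff)
    nat_res = [r for r in native.receptor + native.ligand if r.key in keys]
    decoy_map = decoy.residue_map()
    P, Q = _ca_pairs(nat_res, decoy_map)
    if len(P) < 3:
        raise ContractError(f"fewer than 3 matched interface Calphas ({len(P)})")
    _, _, rmsd = kabsch_superpose(P, Q)
    return rmsd


def lrmsd(decoy: Structure, native: Structure) -> float:
    """Ligand Calpha RMSD with receptors superposed (no ligand fitting)."""
    decoy_map = decoy.residue_map()
    P_rec, Q_rec = _ca_pairs(native.receptor, decoy_map)
    if len(P_rec) < 3:
        raise ContractError(f"fewer than 3 matched receptor Calphas ({len(P_rec)})")
    R, t, _ = kabsch_superpose(P_rec, Q_rec)
    P_lig, Q_lig = _ca_pairs(native.ligand, decoy_map)
    if len(P_lig) == 0:
        raise ContractError("no matched ligand Calphas")
    moved = P_lig @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - Q_lig) ** 2, axis=1))))


def _contact_pairs(structure: Structure, cutoff: float,
                   restrict: set | None = None) -> set[tuple[ResidueKey, ResidueKey]]:
    contacts = set()
    for r_res in structure.receptor:
        rc = r_res.heavy_coords()
        if not len(rc):
            continue
        for l_res in structure.ligand:
            pair = (r_res.key, l_res.key)
            if restrict is not None and pair not in restrict:
                continue
            lc = l_res.heavy_coords()
            if not len(lc):
                continue
            if cdist(rc, lc).min() <= cutoff:
                contacts.add(pair)
    return contacts


def fnat(decoy: Structure, native: Structure,
         contact_cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of native cross-subunit residue contacts kept by the decoy."""
    native_contacts = _contact_pairs(native, contact_cutoff)
    if not native_contacts:
        raise ContractError("native structure has no cross-subunit contacts")
    decoy_map = decoy.residue_map()
    preserved = 0
    for rkey, lkey in native_contacts:
        r_res = decoy_map.get(rkey)
        l_res = decoy_map.get(lkey)
        if r_res is None or l_res is None:
            continue  # missing residue cannot preserve the contact
        rc, lc = r_res.heavy_coords(), l_res.heavy_coords()
        if len(rc) and len(lc) and cdist(rc, lc).min() <= contact_cutoff:
            preserved += 1
    return preserved / len(native_contacts)


def compute_metrics(decoy: Structure, native: Structure,
                    interface_cutoff: float = INTERFACE_RESIDUE_CUTOFF,
                    contact_cutoff: float = CONTACT_CUTOFF) -> CapriMetrics:
    """All three metrics in one call."""
    return CapriMetrics(
        irmsd=irmsd(decoy, native, interface_cutoff),
        lrmsd=lrmsd(decoy, native),
        fnat=fnat(decoy, native, contact_cutoff),
    )
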