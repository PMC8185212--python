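"""Desk-scale synthetic docking decoy sets.

Real decoy archives are large downloads; for development and testing
this module fabricates labeled decoy sets from first principles:

* :func:`make_native` builds a toy two-chain complex of idealized
  poly-alanine strands placed in contact (so the template featurizer
  applies unchanged and the native has a genuine interface);
* :func:`perturb` applies a rigid rotation + translation to the
  ligand subunit only, exactly how rigid-body docking decoys differ
  from the native pose;
* :func:`make_dataset` samples perturbation magnitudes from a
  near-native and a far-from-native regime to hit a requested
  fraction of CAPRI-acceptable decoys, labelling every decoy by
  recomputing its metrics against the native.

Every generated label therefore satisfies
``label == (classify_quality(metrics) >= acceptable)`` by
construction.  The geometry is idealized backbone plus C-beta; side
chains, packing energetics and clash relaxation are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .capri_metrics import CapriMetrics, QualityClass, classify_quality, compute_metrics
from .interface_graph import NoInterfaceError, extract_interface
from .structure_io import Atom, Residue, Structure, write_pdb

# local-frame template of one idealized alanine residue (N, CA, C, O, CB);
# successive residues are translated by _RESIDUE_STEP, which puts the
# C(i)-N(i+1) distance at ~1.33 A (a detectable peptide bond).
_RESIDUE_TEMPLATE = {
    "N": np.array([0.00, 0.00, 0.00]),
    "CA": np.array([1.46, 0.00, 0.00]),
    "C": np.array([2.19, 1.33, 0.00]),
    "O": np.array([1.79, 2.49, 0.00]),
    "CB": np.array([1.06, -0.80, 1.20]),
}
_RESIDUE_STEP = np.array([3.39, 0.75, 0.00])
_CHAIN_SEPARATION = 6.0  # A between the two backbone planes
_LIGAND_SHIFT = np.array([1.70, 0.40, _CHAIN_SEPARATION])
_JITTER = 0.04  # A, uniform coordinate noise for per-target diversity

MIN_NATIVE_CONTACTS = 3
_MAX_TRIES = 40


@dataclass
class PerturbationSpec:
    """Rigid-body ligand perturbation: rotation (degrees) about a random
    axis through the ligand heavy-atom centroid, then a translation."""

    rotation_angle: float
    translation: np.ndarray
    seed: int


@dataclass
class SyntheticDataset:
    target_id: str
    native: Structure
    decoys: list[tuple[Structure, CapriMetrics, str]] = field(default_factory=list)


def _build_chain(chain_id: str, n_res: int, start_serial: int,
                 cb_up: bool, rng: np.random.Generator) -> list[Residue]:
    residues = []
    serial = start_serial
    for i in range(n_res):
        key = (chain_id, i + 1, "")
        res = Residue(key, "ALA")
        for name, local in _RESIDUE_TEMPLATE.items():
            pos = local.copy()
            if name == "CB" and not cb_up:
                pos[2] = -pos[2]
            coords = pos + i * _RESIDUE_STEP + rng.uniform(-_JITTER, _JITTER, 3)
            serial += 1
            res.atoms.append(Atom(serial, name, name[0], coords, key, True))
        residues.append(res)
    return residues


def _count_native_contacts(structure: Structure, cutoff: float = 5.0) -> int:
    from scipy.spatial.distance import cdist

    n = 0
    for r in structure.receptor:
        rc = r.heavy_coords()
        for l in structure.ligand:
            if cdist(rc, l.heavy_coords()).min() <= cutoff:
                n += 1
    return n


def make_native(n_res_receptor: int, n_res_ligand: int, seed: int) -> Structure:
    """Two poly-alanine chains in contact; deterministic given seed."""
    if n_res_receptor < 3 or n_res_ligand < 3:
        raise ValueError("each chain needs at least 3 residues")
    for attempt in range(_MAX_TRIES):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        receptor = _build_chain("A", n_res_receptor, 0, cb_up=True, rng=rng)
        ligand = _build_chain("B", n_res_ligand, 1000, cb_up=False, rng=rng)
        # stagger the ligand along the receptor and lift it by the
        # chain separation; C-betas of the two chains point at each other
        offset = _LIGAND_SHIFT + rng.uniform(-0.2, 0.2, 3) * np.array([1, 1, 0])
        for res in ligand:
            for atom in res.atoms:
                atom.coords = atom.coords + offset
        structure = Structure(receptor, ligand, source_path="synthetic")
        if _count_native_contacts(structure) >= MIN_NATIVE_CONTACTS:
            return structure
    raise RuntimeError("could not place chains in contact")


def perturb(native: Structure, spec: PerturbationSpec) -> Structure:
    """Receptor untouched; ligand rigidly rotated then translated."""
    rng = np.random.default_rng(spec.seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.deg2rad(spec.rotation_angle) * axis).as_matrix()

    out = native.copy()
    lig_coords = np.concatenate([r.heavy_coords() for r in out.ligand])
    centroid = lig_coords.mean(axis=0)
    t = np.asarray(spec.translation, dtype=float)
    for res in out.ligand:
        for atom in res.atoms:
            atom.coords = R @ (atom.coords - centroid) + centroid + t
    return out


def _sample_spec(rng: np.random.Generator, positive: bool) -> PerturbationSpec:
    if positive:
        angle = rng.uniform(0.0, 6.0)
        magnitude = rng.uniform(0.0, 0.8)
    else:
        angle = rng.uniform(30.0, 150.0)
        magnitude = rng.uniform(3.0, 8.0)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return PerturbationSpec(
        rotation_angle=angle,
        translation=direction * magnitude,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_dataset(n_targets: int, decoys_per_target: int,
                 positive_fraction: float, seed: int) -> list[SyntheticDataset]:
    """Labeled decoy sets whose class mix approximates positive_fraction."""
    if not (0.0 < positive_fraction < 1.0):
        raise ValueError("positive_fraction must be in (0, 1)")
    master = np.random.default_rng(seed)
    datasets = []
    for t in range(n_targets):
        target_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(target_seed)
        n_rec = int(rng.integers(6, 9))
        n_lig = int(rng.integers(5, 7))
        native = make_native(n_rec, n_lig, target_seed)
        ds = SyntheticDataset(target_id=f"T{t + 1:02d}", native=native)
        for _ in range(decoys_per_target):
            want_positive = rng.random() < positive_fraction
            decoy = metrics = None
            for _ in range(_MAX_TRIES):
                spec = _sample_spec(rng, want_positive)
                candidate = perturb(native, spec)
                try:
                    extract_interface(candidate)
                except NoInterfaceError:
                    continue
                m = compute_metrics(candidate, native)
                is_positive = classify_quality(m) >= QualityClass.acceptable
                decoy, metrics = candidate, m
                if is_positive == want_positive:
                    break
            if decoy is None:
                raise RuntimeError("could not realize a decoy with an interface")
            label = ("correct" if classify_quality(metrics) >= QualityClass.acceptable
                     else "incorrect")
            ds.decoys.append((decoy, metrics, label))
        datasets.append(ds)
    return datasets


def write_dataset(datasets: list[SyntheticDataset], outdir) -> Path:
    """PDB files plus a manifest TSV usable by the training driver."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ds in enumerate(datasets):
        tdir = outdir / ds.target_id
        tdir.mkdir(exist_ok=True)
        native_path = tdir / "native.pdb"
        write_pdb(ds.native, native_path)
        for j, (decoy, m, label) in enumerate(ds.decoys):
            decoy_path = tdir / f"decoy_{j:04d}.pdb"
            write_pdb(decoy, decoy_path)
            rows.append({
                "target_id": ds.target_id,
                "decoy_id": f"{ds.target_id}/decoy_{j:04d}",
                "decoy_path": str(decoy_path),
                "native_path": str(native_path),
                "label": label,
                "irmsd": round(m.irmsd, 4),
                "lrmsd": round(m.lrmsd, 4),
                "fnat": round(m.fnat, 4),
                "fold": i % 4 + 1,
            })
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
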