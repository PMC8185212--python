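"""Superposition, iRMSD / lRMSD / fnat and CAPRI quality classes."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gatedock import (
    CapriMetrics,
    QualityClass,
    apply_rigid,
    classify_quality,
    compute_metrics,
    fnat,
    irmsd,
    kabsch_superpose,
    lrmsd,
    native_interface_residues,
)
from gatedock.structure_io import Atom, ContractError, Residue, Structure


def _rotation_search_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Independent oracle: minimize RMSD over rotation-vector space."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def objective(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

    best = np.inf
    for x0 in ([0.1, 0.0, 0.0], [1.5, -1.0, 0.5], [-2.0, 2.0, 1.0],
               [0.0, 3.0, 0.0]):
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self, rng):
        P = rng.normal(size=(6, 3))
        _, _, rmsd = kabsch_superpose(P, P.copy())
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_exact_transform(self, rng):
        P = rng.normal(size=(5, 3))
        R_true = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        t_true = np.array([1.0, -2.0, 0.5])
        Q = P @ R_true.T + t_true
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, R_true, atol=1e-9)
        assert np.allclose(t, t_true, atol=1e-9)

    @pytest.mark.parametrize("m", [4, 5])
    def test_matches_rotation_search_oracle(self, m):
        rng = np.random.default_rng(60 + m)
        P = rng.normal(size=(m, 3))
        Q = rng.normal(size=(m, 3))
        _, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(_rotation_search_rmsd(P, Q), abs=1e-6)

    def test_proper_rotation_even_for_reflected_sets(self, rng):
        P = rng.normal(size=(5, 3))
        Q = P * np.array([1.0, 1.0, -1.0])  # mirror image
        R, _, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ContractError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestInterfaceResidues:
    def test_contact_pair_included_far_residue_excluded(self, toy_native):
        keys = native_interface_residues(toy_native)
        assert keys  # toy native is built in contact
        moved = toy_native.copy()
        for atom in moved.receptor[0].atoms:
            atom.coords = atom.coords + np.array([0.0, 0.0, -50.0])
        keys2 = native_interface_residues(moved)
        assert moved.receptor[0].key not in keys2

    def test_missing_decoy_residue_raises(self, toy_native):
        decoy = toy_native.copy()
        for res in decoy.receptor + decoy.ligand:  # renumber everything
            res.key = (res.key[0], res.key[1] + 100, res.key[2])
            for atom in res.atoms:
                atom.residue_key = res.key
        with pytest.raises(ContractError, match="unmatched residue"):
            irmsd(decoy, toy_native)


class TestRmsd:
    def test_identical_structures_have_zero_metrics(self, toy_native):
        m = compute_metrics(toy_native, toy_native)
        assert m.irmsd == pytest.approx(0.0, abs=1e-9)
        assert m.lrmsd == pytest.approx(0.0, abs=1e-9)
        assert m.fnat == 1.0
        assert classify_quality(m) is QualityClass.high

    def test_lrmsd_of_pure_translation_is_its_norm(self, toy_native):
        t = np.array([1.2, -0.7, 2.1])
        decoy = apply_rigid(toy_native, np.eye(3), t, which="ligand")
        assert lrmsd(decoy, toy_native) == pytest.approx(np.linalg.norm(t),
                                                         abs=1e-12)

    def test_irmsd_matches_independent_recomputation(self, toy_native):
        decoy = apply_rigid(toy_native, np.eye(3),
                            np.array([2.0, 0.0, 0.0]), which="ligand")
        value = irmsd(decoy, toy_native)
        # independent recomputation: collect interface CAs, superpose with
        # scipy's orthogonal Procrustes route
        keys = native_interface_residues(toy_native)
        nat = {r.key: r for r in toy_native.receptor + toy_native.ligand}
        dec = {r.key: r for r in decoy.receptor + decoy.ligand}
        P = np.array([dec[k].get("CA").coords for k in sorted(keys)])
        Q = np.array([nat[k].get("CA").coords for k in sorted(keys)])
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        expected = rssd / np.sqrt(len(P))
        assert value == pytest.approx(expected, abs=1e-9)

    def test_lrmsd_of_rotated_ligand_matches_oracle(self, toy_native):
        R = Rotation.from_euler("xyz", [180, 0, 0], degrees=True).as_matrix()
        lig = np.concatenate([r.heavy_coords() for r in toy_native.ligand])
        centroid = lig.mean(axis=0)
        decoy = toy_native.copy()
        for res in decoy.ligand:
            for atom in res.atoms:
                atom.coords = R @ (atom.coords - centroid) + centroid
        value = lrmsd(decoy, toy_native)
        # receptor is untouched, so superposition is the identity and the
        # ligand RMSD is the direct coordinate RMSD
        P = np.array([r.get("CA").coords for r in decoy.ligand])
        Q = np.array([r.get("CA").coords for r in toy_native.ligand])
        expected = np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1)))
        assert value == pytest.approx(expected, abs=1e-9)

    def test_metrics_invariant_under_common_rigid_motion(self, toy_native, rng):
        decoy = apply_rigid(toy_native, np.eye(3),
                            np.array([1.5, 0.5, -1.0]), which="ligand")
        m0 = compute_metrics(decoy, toy_native)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-30, 30, 3)
        moved = apply_rigid(decoy, R, t, which="both")
        m1 = compute_metrics(moved, toy_native)
        assert m1.irmsd == pytest.approx(m0.irmsd, abs=1e-9)
        assert m1.lrmsd == pytest.approx(m0.lrmsd, abs=1e-9)
        assert m1.fnat == m0.fnat


def _point_residue(chain, num, x, y, z, name="GLY"):
    key = (chain, num, "")
    res = Residue(key, name)
    res.atoms.append(Atom(num, "CA", "C", np.array([x, y, z], dtype=float),
                          key, True))
    return res


class TestFnat:
    def _toy_complex(self):
        """4 native contacts: receptor CA atoms at x=0..3 paired with
        ligand CA atoms 4 A above."""
        receptor = [_point_residue("A", i + 1, 8.0 * i, 0, 0) for i in range(4)]
        ligand = [_point_residue("B", i + 1, 8.0 * i, 0, 4.0) for i in range(4)]
        return Structure(receptor, ligand, "toy")

    def test_native_against_itself_is_one(self):
        s = self._toy_complex()
        assert fnat(s, s) == 1.0

    def test_half_of_native_contacts_preserved(self):
        native = self._toy_complex()
        decoy = native.copy()
        for res in decoy.ligand[2:]:  # break 2 of the 4 contacts
            for atom in res.atoms:
                atom.coords = atom.coords + np.array([0.0, 0.0, 20.0])
        assert fnat(decoy, native) == 0.5

    def test_far_away_ligand_scores_zero(self):
        native = self._toy_complex()
        decoy = apply_rigid(native, np.eye(3),
                            np.array([0.0, 0.0, 100.0]), which="ligand")
        assert fnat(decoy, native) == 0.0

    def test_native_without_contacts_is_an_error(self):
        receptor = [_point_residue("A", 1, 0, 0, 0)]
        ligand = [_point_residue("B", 1, 0, 0, 8.0)]
        with pytest.raises(ContractError):
            fnat(Structure(receptor, ligand, "x"),
                 Structure(receptor, ligand, "x"))


class TestClassification:
    @pytest.mark.parametrize("triple,expected", [
        ((2.54, 2.93, 0.551), QualityClass.medium),
        ((2.14, 3.86, 0.453), QualityClass.medium),
        ((0.8, 0.9, 0.6), QualityClass.high),
        ((3.5, 9.0, 0.2), QualityClass.acceptable),
        ((9.0, 20.0, 0.05), QualityClass.incorrect),
        ((20.0, 40.0, 0.0), QualityClass.incorrect),
    ])
    def test_threshold_table(self, triple, expected):
        m = CapriMetrics(irmsd=triple[0], lrmsd=triple[1], fnat=triple[2])
        assert classify_quality(m) is expected

    def test_fnat_floor_dominates(self):
        m = CapriMetrics(irmsd=0.0, lrmsd=0.0, fnat=0.05)
        assert classify_quality(m) is QualityClass.incorrect

    def test_monotone_in_each_metric(self, rng):
        for _ in range(200):
            m = CapriMetrics(irmsd=rng.uniform(0, 12),
                             lrmsd=rng.uniform(0, 15),
                             fnat=rng.uniform(0, 1))
            base = classify_quality(m)
            better_i = CapriMetrics(m.irmsd * 0.5, m.lrmsd, m.fnat)
            better_l = CapriMetrics(m.irmsd, m.lrmsd * 0.5, m.fnat)
            better_f = CapriMetrics(m.irmsd, m.lrmsd,
                                    min(m.fnat + 0.2, 1.0))
            assert classify_quality(better_i) >= base
            assert classify_quality(better_l) >= base
            assert classify_quality(better_f) >= base
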