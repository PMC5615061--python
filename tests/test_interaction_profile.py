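"""Hydrogen-bond detection, fingerprints, triage and energy decomposition."""

import numpy as np
import pytest

from conftest import brute_force_pair_energy
from ogtscreen.interaction_profile import (
    COULOMB_K,
    HBondCriteria,
    LigandAtom,
    Pose,
    TriageRule,
    contact_fingerprint,
    detect_hbonds,
    pair_energy,
    per_residue_energy,
    triage_key_residues,
)
from ogtscreen.structure_align import AtomSite, Residue, StructureModel


def receptor_with_site(polar="NZ", element="N", with_h=True, resname="LYS", resnum=842):
    """One-residue receptor: polar atom at origin, optional H along +x."""
    atoms = [AtomSite("CA", "C", (-3.0, 0.0, 0.0)), AtomSite(polar, element, (0.0, 0.0, 0.0))]
    if with_h:
        atoms.append(AtomSite("HZ", "H", (1.0, 0.0, 0.0)))
    return StructureModel("r", {"A": [Residue(resname, resnum, "", tuple(atoms))]})


def ligand_acceptor_at(x, y=0.0, z=0.0):
    return Pose("L", "p", [LigandAtom(0, "O", (x, y, z))])


class TestHBondDetection:
    def test_good_geometry_detected(self):
        # donor at origin, H at +1x, acceptor nearly collinear: DHA ~ 170 deg
        rec = receptor_with_site()
        acc = ligand_acceptor_at(2.78, 0.24)  # |DA| ~ 2.79, angle ~ 172 deg
        bonds = detect_hbonds(acc, rec)
        assert any(b.donor.endswith("/NZ") for b in bonds)
        b = next(b for b in bonds if b.donor.endswith("/NZ"))
        assert b.distance <= 3.5 and b.angle > 160

    def test_beyond_distance_cutoff_not_detected(self):
        rec = receptor_with_site()
        assert detect_hbonds(ligand_acceptor_at(5.0), rec) == []

    def test_bad_angle_not_detected(self):
        # acceptor perpendicular to the D-H axis at H: DHA = 90 deg
        rec = receptor_with_site()
        acc = ligand_acceptor_at(1.0, 2.6)  # |DA| ~ 2.79 but angle at H = 90
        bonds = [b for b in bonds_from(acc, rec) if b.angle is not None]
        assert bonds == []

    def test_no_polar_atoms_is_empty_not_error(self):
        rec = receptor_with_site()
        apolar = Pose("L", "p", [LigandAtom(0, "C", (2.8, 0, 0))])
        assert detect_hbonds(apolar, rec) == []

    def test_distance_only_mode_without_hydrogens(self):
        rec = receptor_with_site(with_h=False)
        bonds = detect_hbonds(ligand_acceptor_at(2.8), rec)
        assert len(bonds) >= 1
        assert all(b.angle is None for b in bonds)

    def test_matches_brute_force_scan_on_random_complexes(self, toy_complex):
        """No shortcut may drop pairs an exhaustive scan would find."""
        rng = np.random.default_rng(21)
        criteria = HBondCriteria()
        _spec, receptor, _pose, _truth = toy_complex
        for _ in range(25):
            n = int(rng.integers(1, 6))
            atoms = [
                LigandAtom(i, rng.choice(["O", "N", "C"]), tuple(rng.uniform(-8, 8, 3)))
                for i in range(n)
            ]
            pose = Pose("L", "p", atoms)
            got = {(b.donor, b.acceptor) for b in detect_hbonds(pose, receptor, criteria)}
            expected = brute_force_hbonds(pose, receptor, criteria)
            assert got == expected


def bonds_from(pose, rec):
    return detect_hbonds(pose, rec)


def brute_force_hbonds(pose, receptor, criteria):
    """O(n^2) re-derivation of the distance-only H-bond calls (H-less pose)."""
    pairs = set()
    lig_polar = [(f"LIG:{a.index}", np.array(a.coord)) for a in pose.atoms if a.element in "NO"]
    for chain, res in receptor.iter_residues():
        h_sites = [np.array(a.coord) for a in res.atoms if a.element == "H"]
        for a in res.atoms:
            if a.element not in "NO":
                continue
            label = f"{chain}/{res.name}{res.number}/{a.name}"
            rc = np.array(a.coord)
            has_h = any(np.linalg.norm(h - rc) <= 1.3 for h in h_sites)
            for ll, lc in lig_polar:
                d = float(np.linalg.norm(lc - rc))
                if d > criteria.max_da_distance:
                    continue
                pairs.add((ll, label))  # H-less ligand: distance-only both ways
                if has_h:
                    h = min(h_sites, key=lambda hh: np.linalg.norm(hh - rc))
                    v1, v2 = rc - h, lc - h
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= criteria.min_dha_angle:
                        pairs.add((label, ll))
                else:
                    pairs.add((label, ll))
    return pairs


class TestFingerprintAndTriage:
    def test_planted_bond_marks_only_that_residue(self, toy_complex):
        _spec, receptor, pose, truth = toy_complex
        fp = contact_fingerprint(pose, receptor)
        bonded = {(name, num) for (_c, num, name), c in fp.residues.items() if c.has_hbond}
        assert bonded == set(truth)

    def test_hbond_implies_polar_contact(self, toy_complex):
        _spec, receptor, pose, _truth = toy_complex
        fp = contact_fingerprint(pose, receptor)
        for c in fp.residues.values():
            assert (not c.has_hbond) or c.has_polar_contact

    def test_apolar_ligand_all_clear(self, toy_complex):
        _spec, receptor, _pose, _truth = toy_complex
        apolar = Pose("L", "p", [LigandAtom(0, "C", (0.0, 0.0, 0.0))])
        fp = contact_fingerprint(apolar, receptor)
        assert not any(c.has_hbond or c.has_polar_contact for c in fp.residues.values())

    def test_triage_any_mode(self, toy_complex):
        _spec, receptor, pose, _truth = toy_complex  # planted contact: Lys842
        fp = contact_fingerprint(pose, receptor)
        ok, matched = triage_key_residues(fp, TriageRule())
        assert ok and ("LYS", 842) in matched

    def test_triage_all_mode_fails_on_partial_contacts(self, toy_complex):
        _spec, receptor, pose, _truth = toy_complex
        fp = contact_fingerprint(pose, receptor)
        ok, _ = triage_key_residues(fp, TriageRule(mode="all"))
        assert not ok

    def test_triage_fail_when_no_key_contacts(self, toy_complex):
        _spec, receptor, _pose, _truth = toy_complex
        apolar = Pose("L", "p", [LigandAtom(0, "C", (0.0, 0.0, 0.0))])
        fp = contact_fingerprint(apolar, receptor)
        ok, matched = triage_key_residues(fp, TriageRule())
        assert not ok and matched == []

    def test_required_residue_absent_is_error(self, toy_complex):
        _spec, receptor, pose, _truth = toy_complex
        fp = contact_fingerprint(pose, receptor)
        with pytest.raises(ValueError, match="999"):
            triage_key_residues(fp, TriageRule(frozenset({("TRP", 999)})))


class TestEnergyDecomposition:
    def test_coulomb_closed_form(self):
        # charges +0.5/-0.5 at 3.32 A, no LJ: 332.0636 * (-0.25) / 3.32
        rec = StructureModel(
            "r", {"A": [Residue("GLY", 1, "", (AtomSite("N", "N", (3.32, 0, 0)),))]}
        )
        pose = Pose("L", "p", [LigandAtom(0, "O", (0.0, 0.0, 0.0), charge=0.5)])
        charges = {("A", 1, "GLY", "N"): -0.5}
        energies, total = per_residue_energy(
            pose, rec, receptor_charges=charges, include_lj=False
        )
        assert total == pytest.approx(-25.0, abs=0.01)

    def test_lj_minimum_equals_minus_epsilon(self):
        table = {"O": (1.7, 0.21), "N": (1.85, 0.17)}
        rmin = 1.7 + 1.85
        eps = np.sqrt(0.21 * 0.17)
        e = pair_energy(0.0, 0.0, 1.7, 0.21, 1.85, 0.17, rmin)
        assert e == pytest.approx(-eps, rel=1e-12)

    def test_beyond_cutoff_is_zero(self):
        rec = StructureModel(
            "r", {"A": [Residue("GLY", 1, "", (AtomSite("N", "N", (20.0, 0, 0)),))]}
        )
        pose = Pose("L", "p", [LigandAtom(0, "O", (0.0, 0.0, 0.0), charge=0.5)])
        energies, total = per_residue_energy(pose, rec, cutoff=10.0)
        assert total == 0.0 and all(v == 0.0 for v in energies.values())

    def test_unknown_element_is_error(self):
        rec = StructureModel(
            "r", {"A": [Residue("GLY", 1, "", (AtomSite("X", "Xx", (3.0, 0, 0)),))]}
        )
        pose = Pose("L", "p", [LigandAtom(0, "O", (0.0, 0.0, 0.0))])
        with pytest.raises(ValueError, match="Xx"):
            per_residue_energy(pose, rec)

    def test_per_residue_sum_matches_flat_double_loop(self, toy_complex):
        rng = np.random.default_rng(22)
        _spec, receptor, _pose, _truth = toy_complex
        for _ in range(20):
            atoms = [
                LigandAtom(i, rng.choice(["C", "N", "O"]), tuple(rng.uniform(-6, 6, 3)),
                           charge=float(rng.uniform(-0.5, 0.5)))
                for i in range(int(rng.integers(1, 6)))
            ]
            pose = Pose("L", "p", atoms)
            energies, total = per_residue_energy(pose, receptor, cutoff=12.0)
            assert sum(energies.values()) == pytest.approx(total, rel=1e-12)
            oracle = brute_force_pair_energy(pose, receptor, 12.0, 1.0, None, None)
            assert total == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_invariance_under_joint_rigid_motion(self, toy_complex):
        from ogtscreen.structure_align import StructureModel as SM, Residue as R, AtomSite as A

        _spec, receptor, pose, _truth = toy_complex
        theta = 0.9
        Rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        t = np.array([5.0, -3.0, 2.0])

        def move(xyz):
            return tuple(np.asarray(xyz) @ Rz.T + t)

        rec2 = SM(receptor.id, {
            c: [R(r.name, r.number, r.icode,
                  tuple(A(a.name, a.element, move(a.coord)) for a in r.atoms))
                for r in residues]
            for c, residues in receptor.chains.items()
        })
        pose2 = Pose(pose.ligand_id, pose.pose_id,
                     [LigandAtom(a.index, a.element, move(a.coord), a.charge)
                      for a in pose.atoms])
        _e1, t1 = per_residue_energy(pose, receptor)
        _e2, t2 = per_residue_energy(pose2, rec2)
        assert t1 == pytest.approx(t2, rel=1e-9)
        hb1 = {(b.donor, b.acceptor) for b in detect_hbonds(pose, receptor)}
        hb2 = {(b.donor, b.acceptor) for b in detect_hbonds(pose2, rec2)}
        assert hb1 == hb2

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(max_da_distance=-1.0)
        with pytest.raises(ValueError):
            HBondCriteria(min_dha_angle=200.0)
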