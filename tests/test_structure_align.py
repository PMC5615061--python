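"""PDB parsing, Kabsch superposition, pose RMSD and clustering."""

import numpy as np
import pytest

from conftest import quaternion_superpose_rmsd
from ogtscreen.structure_align import (
    cluster_poses,
    kabsch_superpose,
    parse_pdb,
    parse_multi_model_pdb,
    pose_rmsd,
    superpose_structures,
)

PDB_ONE_ATOM = (
    "ATOM      1  CA  PRO A 559      10.000  20.000  30.000  1.00  0.00           C\n"
)

PDB_ALTLOC = (
    "ATOM      1  CA APRO A 559      10.000  20.000  30.000  0.60  0.00           C\n"
    "ATOM      2  CA BPRO A 559      11.000  21.000  31.000  0.40  0.00           C\n"
)


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


class TestPdbParsing:
    def test_single_atom_record(self):
        model = parse_pdb(PDB_ONE_ATOM)
        res = model.get_residue("A", 559)
        assert res is not None and res.name == "PRO"
        ca = res.get_atom("CA")
        assert ca.coord == pytest.approx((10.0, 20.0, 30.0))
        assert ca.element == "C"

    def test_altloc_keep_first(self):
        model = parse_pdb(PDB_ALTLOC)
        res = model.get_residue("A", 559)
        assert len(res.atoms) == 1
        assert res.atoms[0].coord == pytest.approx((10.0, 20.0, 30.0))

    def test_empty_file_is_error(self):
        with pytest.raises(ValueError):
            parse_pdb("")

    def test_hetatm_ligand_retained(self):
        text = PDB_ONE_ATOM + (
            "HETATM    2  O1  LIG A 900       1.000   2.000   3.000  1.00  0.00           O\n"
        )
        model = parse_pdb(text)
        lig = model.get_residue("A", 900)
        assert lig is not None and lig.name == "LIG"

    def test_multi_model_pose_set(self):
        text = "MODEL 1\n" + PDB_ONE_ATOM + "ENDMDL\nMODEL 2\n" + (
            "ATOM      1  CA  PRO A 559      13.000  24.000  30.000  1.00  0.00           C\n"
        ) + "ENDMDL\n"
        poses = parse_multi_model_pdb(text)
        assert len(poses) == 2
        assert pose_rmsd(poses[0], poses[1]) == pytest.approx(5.0)


class TestKabsch:
    def test_identical_point_sets(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        s = kabsch_superpose(P, P)
        assert s.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(s.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(s.translation, 0.0, atol=1e-10)

    def test_recovers_known_rotation(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about z
        Q = P @ Rz.T
        s = kabsch_superpose(P, Q)
        assert np.allclose(s.rotation, Rz, atol=1e-8)
        assert s.rmsd == pytest.approx(0.0, abs=1e-8)

    def test_mirror_image_yields_proper_rotation(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(12, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # reflection: no proper rotation can reach rmsd 0
        s = kabsch_superpose(P, Q)
        assert np.linalg.det(s.rotation) == pytest.approx(1.0, abs=1e-6)
        assert s.rmsd > 0.1

    def test_rotation_is_orthogonal(self):
        rng = np.random.default_rng(5)
        s = kabsch_superpose(rng.normal(size=(8, 3)), rng.normal(size=(8, 3)))
        assert np.allclose(s.rotation @ s.rotation.T, np.eye(3), atol=1e-10)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            n = int(rng.integers(3, 51))
            P = rng.normal(size=(n, 3))
            Q = P @ random_rotation(rng).T + rng.normal(size=3) + rng.normal(
                scale=0.3, size=(n, 3)
            )
            s = kabsch_superpose(P, Q)
            assert abs(s.rmsd - quaternion_superpose_rmsd(P, Q)) < 1e-8

    def test_forward_and_reverse_transforms_are_inverse(self):
        rng = np.random.default_rng(7)
        P = rng.normal(size=(10, 3))
        Q = P @ random_rotation(rng).T + np.array([3.0, -1.0, 2.0])
        fwd = kabsch_superpose(P, Q)
        rev = kabsch_superpose(Q, P)
        assert np.allclose(fwd.rotation @ rev.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(fwd.apply(rev.apply(Q)), Q, atol=1e-6)

    def test_too_few_or_degenerate_points(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)

    def test_structure_superposition_pairs_common_ca(self):
        from ogtscreen.structure_align import AtomSite, Residue, StructureModel

        rng = np.random.default_rng(8)
        coords = rng.normal(size=(6, 3)) * 5
        R = random_rotation(rng)
        t = np.array([1.0, 2.0, 3.0])

        def model(xyz, sid):
            residues = [
                Residue("ALA", 100 + i, "", (AtomSite("CA", "C", tuple(c)),))
                for i, c in enumerate(xyz)
            ]
            return StructureModel(sid, {"A": residues})

        ref = model(coords, "ref")
        mob = model(coords @ R.T + t, "mob")
        s = superpose_structures(mob, ref)
        assert s.rmsd == pytest.approx(0.0, abs=1e-8)
        assert s.n_atoms == 6


class TestPoseRmsd:
    def test_identity_and_translation(self):
        rng = np.random.default_rng(9)
        pose = rng.normal(size=(7, 3))
        assert pose_rmsd(pose, pose) == 0.0
        assert pose_rmsd(pose, pose + np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_single_atom_pose(self):
        assert pose_rmsd([[0.0, 0, 0]], [[2.0, 0, 0]]) == pytest.approx(2.0)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            pose_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            a, b, c = rng.normal(size=(3, 6, 3))
            dab, dba = pose_rmsd(a, b), pose_rmsd(b, a)
            assert dab == pytest.approx(dba)
            assert pose_rmsd(a, c) <= dab + pose_rmsd(b, c) + 1e-12


class TestClustering:
    def test_tight_cloud_plus_outlier(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(5, 3))
        poses = [base + rng.normal(scale=0.2, size=base.shape) for _ in range(3)]
        poses.append(base + np.array([10.0, 0, 0]))
        pc = cluster_poses(poses, threshold=2.0)
        assert pc.cluster_sizes[pc.biggest_cluster] == 3
        assert pc.labels[3] != pc.labels[0]

    def test_identical_poses_form_one_cluster(self):
        base = np.zeros((4, 3))
        pc = cluster_poses([base.copy() for _ in range(5)], threshold=1.0)
        assert pc.cluster_sizes[pc.biggest_cluster] == 5

    def test_all_singletons_tie_broken_by_affinity(self):
        poses = [np.zeros((1, 3)) + [i * 10.0, 0, 0] for i in range(3)]
        pc = cluster_poses(poses, threshold=0.5, pose_ids=["p1", "p2", "p3"],
                           affinities=[-6.0, -9.0, -7.0])
        assert pc.representative == "p2"

    def test_representative_is_best_affinity_in_biggest_cluster(self):
        base = np.zeros((2, 3))
        poses = [base, base + 0.1, base + [5.0, 0, 0]]
        pc = cluster_poses(poses, 1.0, ["a", "b", "c"], affinities=[-7.0, -8.0, -9.5])
        assert pc.representative == "b"  # c is better but outside the biggest cluster

    def test_invariant_under_pose_input_order(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=(4, 3))
        poses = [base + rng.normal(scale=0.1, size=base.shape) for _ in range(4)]
        poses.append(base + np.array([8.0, 0, 0]))
        ids = [f"p{i}" for i in range(5)]
        pc1 = cluster_poses(poses, 2.0, ids)
        order = [4, 2, 0, 3, 1]
        pc2 = cluster_poses([poses[i] for i in order], 2.0, [ids[i] for i in order])
        part1 = {frozenset(i for i in range(5) if pc1.labels[i] == lab) for lab in set(pc1.labels)}
        ids2 = pc2.pose_ids
        part2 = {
            frozenset(int(ids2[i][1:]) for i in range(5) if pc2.labels[i] == lab)
            for lab in set(pc2.labels)
        }
        assert part1 == part2
        assert pc1.representative == pc2.representative
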