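"""Receptor superposition, pose RMSD, and cross-ensemble pose clustering.

The receptor ensemble is brought into a common frame with a least-squares
Kabsch superposition over CA atoms shared by (chain, residue number). A
ligand's docked poses from the 16 receptors, once in that frame, are compared
by plain coordinate RMSD (no re-fitting) and clustered by single linkage:
pose pairs within a threshold (default 2.0 A) are joined and the connected
components form clusters. The biggest cluster's best-scoring member is the
representative pose carried into interaction analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

DEFAULT_CLUSTER_THRESHOLD = 2.0  # Angstrom


@dataclass(frozen=True)
class AtomSite:
    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""


@dataclass(frozen=True)
class Residue:
    name: str
    number: int
    icode: str
    atoms: tuple[AtomSite, ...]

    def get_atom(self, name: str) -> AtomSite | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """One receptor (or ligand) structure: chains -> residues -> atoms."""

    id: str
    chains: dict[str, list[Residue]]

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.number == number and r.icode == icode:
                return r
        return None

    def iter_residues(self):
        for chain_id, residues in self.chains.items():
            for r in residues:
                yield chain_id, r

    def ca_coords_by_key(self) -> dict[tuple[str, int, str], np.ndarray]:
        out = {}
        for chain_id, r in self.iter_residues():
            ca = r.get_atom("CA")
            if ca is not None:
                out[(chain_id, r.number, r.icode)] = np.asarray(ca.coord, dtype=float)
        return out


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map mobile-frame coordinates into the reference frame."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class PoseCluster:
    pose_ids: tuple[str, ...]
    threshold: float
    labels: tuple[int, ...]
    cluster_sizes: dict[int, int]
    biggest_cluster: int
    representative: str


# ---------------------------------------------------------------------------
# PDB parsing (Biopython behind a light container)


def parse_pdb(text: str, structure_id: str = "model") -> StructureModel:
    """Parse PDB text into a StructureModel (first model, keep-first altloc)."""
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    structure = parser.get_structure(structure_id, io.StringIO(text))
    models = list(structure.get_models())
    if not models:
        raise ValueError("no ATOM/HETATM records found")
    model = models[0]
    chains: dict[str, list[Residue]] = {}
    n_atoms = 0
    for chain in model:
        residues = []
        for res in chain:
            atoms = []
            seen_names: set[str] = set()
            for atom in res.get_unpacked_list():
                if atom.get_name() in seen_names:
                    continue  # keep-first altloc policy
                seen_names.add(atom.get_name())
                atoms.append(
                    AtomSite(
                        name=atom.get_name(),
                        element=(atom.element or "").strip() or atom.get_name()[0],
                        coord=tuple(float(x) for x in atom.coord),
                        occupancy=float(atom.get_occupancy() or 1.0),
                        altloc=atom.get_altloc().strip(),
                    )
                )
            n_atoms += len(atoms)
            het, resnum, icode = res.get_id()
            residues.append(
                Residue(name=res.get_resname().strip(), number=resnum,
                        icode=icode.strip(), atoms=tuple(atoms))
            )
        if residues:
            chains[chain.get_id()] = residues
    if n_atoms == 0:
        raise ValueError("no ATOM/HETATM records found")
    return StructureModel(id=structure_id, chains=chains)


def parse_multi_model_pdb(text: str, structure_id: str = "poses") -> list[np.ndarray]:
    """Coordinate array per MODEL block (pose sets share atom ordering)."""
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    structure = parser.get_structure(structure_id, io.StringIO(text))
    coords = []
    for model in structure:
        xyz = [atom.coord for atom in model.get_atoms()]
        if xyz:
            coords.append(np.asarray(xyz, dtype=float))
    if not coords:
        raise ValueError("no ATOM/HETATM records found")
    return coords


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares optimal proper rotation + translation (Kabsch, via SVD).

    Maps ``mobile`` onto ``reference``: x -> R x + t. The reflection case is
    resolved by flipping the sign of the smallest singular vector so that
    det(R) = +1; the returned rmsd is the residual after the fit.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be equal-length Nx3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    # collinear / rank-deficient configurations have no unique rotation
    if np.linalg.matrix_rank(np.vstack([Pc.T, Qc.T]), tol=1e-10) < 2:
        raise ValueError("degenerate (collinear or coincident) point configuration")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    fitted = Pc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Qc) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def superpose_structures(mobile: StructureModel, reference: StructureModel) -> Superposition:
    """Superpose on CA atoms of residues shared by (chain, number, icode)."""
    ca_m = mobile.ca_coords_by_key()
    ca_r = reference.ca_coords_by_key()
    common = sorted(set(ca_m) & set(ca_r))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} common CA atoms between {mobile.id} and {reference.id}"
        )
    P = np.array([ca_m[k] for k in common])
    Q = np.array([ca_r[k] for k in common])
    return kabsch_superpose(P, Q)


# ---------------------------------------------------------------------------
# pose RMSD and clustering


def pose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Coordinate RMSD between same-ordering poses; no superposition applied."""
    A = np.atleast_2d(np.asarray(a, dtype=float))
    B = np.atleast_2d(np.asarray(b, dtype=float))
    if A.shape != B.shape:
        raise ValueError(f"pose shapes differ: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def rmsd_matrix(poses: list[np.ndarray]) -> np.ndarray:
    n = len(poses)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pose_rmsd(poses[i], poses[j])
    return M


def cluster_poses(
    poses: list[np.ndarray],
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    pose_ids: list[str] | None = None,
    affinities: list[float] | None = None,
) -> PoseCluster:
    """Single-linkage pose clustering at an RMSD threshold.

    Clusters are connected components of the graph joining pose pairs with
    RMSD <= threshold. The biggest cluster is selected (ties go to the
    cluster containing the most negative affinity member, then lowest pose
    id); its representative is the member with the most negative affinity
    (fallback: lowest pose id).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(poses)
    if n == 0:
        raise ValueError("need at least one pose")
    if pose_ids is None:
        pose_ids = [f"pose{i+1}" for i in range(n)]
    M = rmsd_matrix(poses)
    adj = csr_matrix(M <= threshold)
    _, raw = connected_components(adj, directed=False)
    # relabel components deterministically by order of first appearance
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap)
        labels.append(remap[r])
    sizes: dict[int, int] = {}
    for lab in labels:
        sizes[lab] = sizes.get(lab, 0) + 1
    max_size = max(sizes.values())
    candidates = [lab for lab, s in sizes.items() if s == max_size]
    if len(candidates) > 1 and affinities is not None:
        best_aff = {
            lab: min(affinities[i] for i in range(n) if labels[i] == lab)
            for lab in candidates
        }
        candidates.sort(key=lambda lab: (best_aff[lab],
                                         min(pose_ids[i] for i in range(n) if labels[i] == lab)))
    else:
        candidates.sort(key=lambda lab: min(pose_ids[i] for i in range(n) if labels[i] == lab))
    biggest = candidates[0]
    members = [i for i in range(n) if labels[i] == biggest]
    if affinities is not None:
        rep = min(members, key=lambda i: (affinities[i], pose_ids[i]))
    else:
        rep = min(members, key=lambda i: pose_ids[i])
    return PoseCluster(
        pose_ids=tuple(pose_ids),
        threshold=threshold,
        labels=tuple(labels),
        cluster_sizes=sizes,
        biggest_cluster=biggest,
        representative=pose_ids[rep],
    )


def cluster_report_rows(ligand_id: str, pc: PoseCluster) -> list[dict]:
    """Rows for the cluster report TSV."""
    return [
        {
            "ligand_id": ligand_id,
            "pose_id": pid,
            "cluster_label": lab,
            "cluster_size": pc.cluster_sizes[lab],
            "is_biggest": lab == pc.biggest_cluster,
            "is_representative": pid == pc.representative,
        }
        for pid, lab in zip(pc.pose_ids, pc.labels)
    ]
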