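"""Synthetic inputs with ground truth known by construction.

Every pipeline stage can be exercised without external downloads:

* :func:`gen_library` assembles molecules compositionally (ring units give
  the ring-system count, hydroxyls give donors, ether oxygens give extra
  acceptors, alkyl padding sets MW, optional charged groups set ionisation),
  recording each descriptor's true value next to the SMILES.
* :func:`gen_score_matrix` plants actives in a ligand x receptor affinity
  table: active latent affinities ~ Normal(-9.0, 0.5) kcal/mol, decoys
  ~ Normal(-6.0, 1.0), with receptor-level jitter and non-negative pose-level
  offsets so the best pose per receptor is the latent draw by construction.
* :func:`gen_toy_complex` builds a toy UDP-pocket with residues named after
  the key OGT positions and plants hydrogen bonds at chosen geometries.
* :func:`gen_assay_data` wraps the assay simulator with the study dose grids.

Each generator draws from its own stream derived from the top-level seed by
a fixed offset, so adding one never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .assay_models import (
    DEFAULT_DOSE_GRID,
    DEFAULT_SUBSTRATE_GRID,
    DoseResponse,
    InhibitionModel,
    simulate_dose_response,
)
from .structure_align import AtomSite, Residue, StructureModel
from .interaction_profile import LigandAtom, Pose

_STREAM_OFFSETS = {"library": 1, "scores": 2, "complex": 3, "assay": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(int(seed) * 16 + _STREAM_OFFSETS[stream])


# ---------------------------------------------------------------------------
# compound library


@dataclass(frozen=True)
class LibrarySpec:
    seed: int = 0
    n_molecules: int = 1000
    # marginal probability that a molecule passes each rule
    pass_fraction_mw: float = 0.6
    pass_fraction_charge: float = 0.8
    pass_fraction_rings: float = 0.7
    pass_fraction_hbonds: float = 0.7


_RING_UNITS = {
    # SMILES fragment with one open attachment written as leading atom,
    # ring-system count, free substitution slots
    "benzene": ("c1ccccc1", 1, 4),
    "naphthalene": ("c1ccc2ccccc2c1", 1, 6),
}


class InfeasibleMoleculeError(ValueError):
    """Requested substituent counts exceed available ring positions."""


def build_molecule(
    n_ring_units: int,
    n_hydroxyl: int,
    n_ether: int,
    n_alkyl: int = 0,
    charge_group: str | None = None,
    use_naphthalene_first: bool = False,
    mol_id: str = "mol",
):
    """Assemble one molecule from counted parts; returns (rdkit Mol, truth dict).

    Ring units are joined by single (non-ring) bonds, so the number of ring
    systems equals ``n_ring_units``. Hydroxyls contribute one donor and one
    acceptor each; ether (OCH3) groups one acceptor; the alkyl tail and the
    optional charged group ([NH3+] / carboxylate / both) are attached to ring
    carbons. Raises InfeasibleMoleculeError when the substituents outnumber
    the free ring positions.
    """
    if n_ring_units < 0 or n_hydroxyl < 0 or n_ether < 0 or n_alkyl < 0:
        raise ValueError("all counts must be non-negative")
    rw = Chem.RWMol()
    ring_free_slots: list[int] = []  # atom indices available for substitution
    ring_systems = 0
    prev_attach = None
    for u in range(max(n_ring_units, 0)):
        unit = "naphthalene" if (use_naphthalene_first and u == 0) else "benzene"
        frag_smiles, n_sys, _slots = _RING_UNITS[unit]
        frag = Chem.MolFromSmiles(frag_smiles)
        amap = {}
        for a in frag.GetAtoms():
            idx = rw.AddAtom(Chem.Atom(a.GetAtomicNum()))
            rw.GetAtomWithIdx(idx).SetIsAromatic(a.GetIsAromatic())
            amap[a.GetIdx()] = idx
        for b in frag.GetBonds():
            rw.AddBond(amap[b.GetBeginAtomIdx()], amap[b.GetEndAtomIdx()], b.GetBondType())
        ring_systems += n_sys
        # only unsubstituted CH positions (degree 2 in the fragment) can
        # take a new bond; fused bridgehead carbons are already 3-coordinate
        atoms = sorted(
            amap[a.GetIdx()] for a in frag.GetAtoms() if a.GetDegree() == 2
        )
        if prev_attach is not None:
            rw.AddBond(prev_attach, atoms[0], Chem.BondType.SINGLE)
            atoms = atoms[1:]
        prev_attach = atoms[-1]
        ring_free_slots.extend(atoms[:-1])
    if n_ring_units == 0:
        # acyclic scaffold: a short carbon chain
        c0 = rw.AddAtom(Chem.Atom(6))
        c1 = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(c0, c1, Chem.BondType.SINGLE)
        ring_free_slots = [c0, c1]
        prev_attach = c1

    def take_slot() -> int:
        if not ring_free_slots:
            raise InfeasibleMoleculeError(
                f"{mol_id}: substituents exceed available attachment positions"
            )
        return ring_free_slots.pop(0)

    n_donors = 0
    n_acceptors = 0
    for _ in range(n_hydroxyl):
        at = take_slot()
        o = rw.AddAtom(Chem.Atom(8))
        rw.AddBond(at, o, Chem.BondType.SINGLE)
        n_donors += 1
        n_acceptors += 1
    for _ in range(n_ether):
        at = take_slot()
        o = rw.AddAtom(Chem.Atom(8))
        c = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(at, o, Chem.BondType.SINGLE)
        rw.AddBond(o, c, Chem.BondType.SINGLE)
        n_acceptors += 1
    net_charge = 0
    is_zwitterion = False
    if charge_group in ("cation", "zwitterion"):
        at = take_slot()
        n = rw.AddAtom(Chem.Atom(7))
        rw.GetAtomWithIdx(n).SetFormalCharge(1)
        rw.AddBond(at, n, Chem.BondType.SINGLE)
        net_charge += 1
        n_donors += 1
        n_acceptors += 1
    if charge_group in ("anion", "zwitterion"):
        at = take_slot()
        c = rw.AddAtom(Chem.Atom(6))
        o1 = rw.AddAtom(Chem.Atom(8))
        o2 = rw.AddAtom(Chem.Atom(8))
        rw.GetAtomWithIdx(o2).SetFormalCharge(-1)
        rw.AddBond(at, c, Chem.BondType.SINGLE)
        rw.AddBond(c, o1, Chem.BondType.DOUBLE)
        rw.AddBond(c, o2, Chem.BondType.SINGLE)
        net_charge -= 1
        n_acceptors += 2
    is_zwitterion = charge_group == "zwitterion"
    if n_alkyl > 0:
        at = take_slot()
        prev = at
        for _ in range(n_alkyl):
            c = rw.AddAtom(Chem.Atom(6))
            rw.AddBond(prev, c, Chem.BondType.SINGLE)
            prev = c
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    pt = Chem.GetPeriodicTable()
    mw = sum(
        pt.GetAtomicWeight(a.GetSymbol()) + a.GetTotalNumHs() * pt.GetAtomicWeight("H")
        for a in mol.GetAtoms()
    )
    truth = {
        "mol_id": mol_id,
        "mw": mw,
        "net_charge": net_charge,
        "is_zwitterion": is_zwitterion,
        "n_ring_systems": ring_systems,
        "hba": n_acceptors,
        "hbd": n_donors,
    }
    return mol, truth


def gen_library(spec: LibrarySpec) -> tuple[list[str], pd.DataFrame]:
    """Generate (SMILES list with ids, ground-truth property table).

    Per-rule pass/fail is drawn independently at the spec's fractions and the
    molecule is constructed to satisfy or violate that rule by a wide margin,
    so the truth table also carries the intended pass flags.
    """
    rng = _rng(spec.seed, "library")
    smiles_lines: list[str] = []
    rows: list[dict] = []
    for i in range(spec.n_molecules):
        mol_id = f"SYN{i:06d}"
        want_mw = rng.random() < spec.pass_fraction_mw
        want_charge = rng.random() < spec.pass_fraction_charge
        want_rings = rng.random() < spec.pass_fraction_rings
        want_hb = rng.random() < spec.pass_fraction_hbonds
        n_rings = int(rng.integers(2, 5)) if want_rings else int(rng.choice([0, 1, 5, 6]))
        if want_hb:
            n_oh = int(rng.integers(2, 5))
            n_ether = int(rng.integers(0, 3))
        else:
            n_oh = int(rng.integers(0, 2))  # 0 or 1 donor < 2
            n_ether = int(rng.integers(0, 2))
        if want_charge:
            charge_group = None
        else:
            charge_group = str(rng.choice(["cation", "anion", "zwitterion"]))
        use_naph = bool(rng.random() < 0.3 and n_rings > 0)
        extra_alkyl = int(rng.integers(0, 8))

        def build(n_alkyl):
            try:
                return build_molecule(
                    n_ring_units=n_rings, n_hydroxyl=n_oh, n_ether=n_ether,
                    n_alkyl=n_alkyl, charge_group=charge_group,
                    use_naphthalene_first=use_naph, mol_id=mol_id,
                )
            except InfeasibleMoleculeError:
                return build_molecule(
                    n_ring_units=max(n_rings, 2), n_hydroxyl=n_oh, n_ether=n_ether,
                    n_alkyl=n_alkyl, charge_group=charge_group, mol_id=mol_id,
                )

        # two-pass MW control: measure the bare scaffold, then pad with a
        # CH2 chain (~14.03 Da each) to land inside or outside [250, 600]
        mol, truth = build(0)
        mw0 = truth["mw"]
        if want_mw:
            if mw0 < 255.0:
                n_alkyl = int(np.ceil((300.0 - mw0) / 14.03))
                room = int((590.0 - (mw0 + n_alkyl * 14.03)) // 14.03)
                n_alkyl += min(extra_alkyl, max(room, 0))
            else:
                n_alkyl = min(extra_alkyl, max(int((590.0 - mw0) // 14.03), 0))
        else:
            n_alkyl = 0 if mw0 < 249.0 else int(np.ceil((601.0 - mw0) / 14.03)) + 5
        if n_alkyl > 0:
            mol, truth = build(n_alkyl)
        smiles_lines.append(f"{Chem.MolToSmiles(mol, canonical=False)}\t{mol_id}")
        rows.append(truth)
    return smiles_lines, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# docking score matrices


@dataclass(frozen=True)
class ScoreMatrixSpec:
    seed: int = 0
    n_decoys: int = 4234
    n_actives: int = 10
    n_receptors: int = 16
    active_mean: float = -9.0
    active_sd: float = 0.5
    decoy_mean: float = -6.0
    decoy_sd: float = 1.0
    receptor_jitter_sd: float = 0.3
    poses_per_pair: int = 5
    pose_offset_scale: float = 0.5  # exponential scale of positive offsets

    def __post_init__(self) -> None:
        if self.n_actives < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")


def gen_score_matrix(spec: ScoreMatrixSpec) -> tuple[pd.DataFrame, list[str]]:
    """Long-format pose-score table with planted actives.

    Per ligand a latent affinity is drawn (actives stronger); per receptor
    the best pose is latent + Normal(0, jitter); the remaining poses add
    positive exponential offsets, so best-per-receptor = the jittered latent
    by construction. Returns (table, active ligand ids).
    """
    rng = _rng(spec.seed, "scores")
    n = spec.n_actives + spec.n_decoys
    ids = np.array(
        [f"ACT{i:04d}" for i in range(spec.n_actives)]
        + [f"DEC{i:05d}" for i in range(spec.n_decoys)]
    )
    latent = np.concatenate(
        [
            rng.normal(spec.active_mean, spec.active_sd, spec.n_actives),
            rng.normal(spec.decoy_mean, spec.decoy_sd, spec.n_decoys),
        ]
    )
    R, P = spec.n_receptors, spec.poses_per_pair
    best = latent[:, None] + rng.normal(0.0, spec.receptor_jitter_sd, (n, R))
    offsets = rng.exponential(spec.pose_offset_scale, (n, R, P - 1)) if P > 1 else None
    receptor_ids = [f"REC{r+1:02d}" for r in range(R)]
    frames = []
    lig_rep = np.repeat(ids, R)
    rec_rep = np.tile(receptor_ids, n)
    frames.append(
        pd.DataFrame(
            {
                "ligand_id": lig_rep,
                "receptor_id": rec_rep,
                "pose_rank": 1,
                "affinity": best.ravel(),
            }
        )
    )
    if offsets is not None:
        extra = best[:, :, None] + np.sort(offsets, axis=2)
        for p in range(P - 1):
            frames.append(
                pd.DataFrame(
                    {
                        "ligand_id": lig_rep,
                        "receptor_id": rec_rep,
                        "pose_rank": p + 2,
                        "affinity": extra[:, :, p].ravel(),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return table, [str(x) for x in ids[: spec.n_actives]]


# ---------------------------------------------------------------------------
# toy pocket / pose geometry


@dataclass(frozen=True)
class ToyComplexSpec:
    seed: int = 0
    pocket_radius: float = 8.0  # Angstrom, residues on a ring around origin
    bonded_residues: tuple[tuple[str, int], ...] = (("LYS", 842),)
    hbond_distance: float = 2.8
    hbond_angle: float = 170.0  # donor-H-acceptor, degrees
    n_cluster_poses: int = 5
    cluster_jitter: float = 0.4  # Angstrom, <= threshold/4 keeps the cloud tight
    outlier_shift: float = 10.0


#: the toy pocket's residue roster (name, number): key OGT UDP-pocket residues
TOY_POCKET_RESIDUES: tuple[tuple[str, int], ...] = (
    ("ASN", 557), ("GLN", 839), ("LYS", 842), ("ALA", 897),
    ("LYS", 898), ("HIS", 920), ("THR", 921), ("PHE", 868),
)

_SIDECHAIN_POLAR = {"ASN": "OD1", "GLN": "OE1", "LYS": "NZ", "HIS": "NE2", "THR": "OG1"}


def gen_toy_complex(spec: ToyComplexSpec):
    """Toy pocket + ligand pose with planted hydrogen-bond geometry.

    Residues sit on a ring of ``pocket_radius`` around the origin, each with
    a CA and (for polar residues) a side-chain N/O pointing inward plus a
    hydrogen on the donor. For each residue in ``bonded_residues`` a ligand
    oxygen is placed along the inward axis at ``hbond_distance`` from the
    polar atom with the planted donor-H-acceptor angle. Returns
    (StructureModel, Pose, truth) where truth lists the planted residues.
    """
    for rname, rnum in spec.bonded_residues:
        if (rname, rnum) not in TOY_POCKET_RESIDUES:
            raise ValueError(f"{rname}{rnum} is not in the toy pocket roster")
        if rname not in _SIDECHAIN_POLAR:
            raise ValueError(f"{rname} has no polar side-chain site to bond")
    if spec.hbond_distance <= 1.2:
        raise ValueError("planted H-bond distance must exceed the X-H bond length")
    nres = len(TOY_POCKET_RESIDUES)
    residues = []
    lig_atoms: list[LigandAtom] = []
    truth: list[tuple[str, int]] = []
    lig_idx = 0
    # a central apolar anchor atom so the ligand is never empty
    lig_atoms.append(LigandAtom(lig_idx, "C", (0.0, 0.0, 0.0), charge=0.0))
    lig_idx += 1
    for k, (rname, rnum) in enumerate(TOY_POCKET_RESIDUES):
        theta = 2.0 * np.pi * k / nres
        pos = np.array([spec.pocket_radius * np.cos(theta),
                        spec.pocket_radius * np.sin(theta), 0.0])
        inward = -pos / np.linalg.norm(pos)
        atoms = [AtomSite("CA", "C", tuple(pos))]
        polar_name = _SIDECHAIN_POLAR.get(rname)
        if polar_name is not None:
            polar_pos = pos + inward * 2.0
            atoms.append(AtomSite(polar_name, polar_name[0], tuple(polar_pos)))
            h_pos = polar_pos + inward * 1.0
            atoms.append(AtomSite("H" + polar_name[1:], "H", tuple(h_pos)))
            if (rname, rnum) in spec.bonded_residues:
                # acceptor along the D-H axis, bent to the planted angle at H
                bend = np.deg2rad(180.0 - spec.hbond_angle)
                perp = np.array([-inward[1], inward[0], 0.0])
                if np.linalg.norm(perp) < 1e-9:
                    perp = np.array([1.0, 0.0, 0.0])
                direction = np.cos(bend) * inward + np.sin(bend) * perp
                # distance measured donor->acceptor; acceptor placed from H
                ha = _solve_ha_distance(spec.hbond_distance, 1.0, spec.hbond_angle)
                acc_pos = h_pos + direction * ha
                lig_atoms.append(LigandAtom(lig_idx, "O", tuple(acc_pos), charge=-0.4))
                lig_idx += 1
                truth.append((rname, rnum))
        residues.append(Residue(rname, rnum, "", tuple(atoms)))
    receptor = StructureModel(id="TOYPOCKET", chains={"A": residues})
    pose = Pose(ligand_id="TOYLIG", pose_id="pose1", atoms=lig_atoms)
    return receptor, pose, truth


def _solve_ha_distance(d_da: float, d_dh: float, angle_deg: float) -> float:
    """H-acceptor distance giving donor-acceptor distance d_da at the DHA angle."""
    # law of cosines in triangle D-H-A with the angle at H
    gamma = np.deg2rad(angle_deg)
    # d_da^2 = d_dh^2 + x^2 - 2 d_dh x cos(gamma)
    a, b, c = 1.0, -2.0 * d_dh * np.cos(gamma), d_dh**2 - d_da**2
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("infeasible H-bond geometry")
    return (-b + np.sqrt(disc)) / (2 * a)


def gen_pose_cloud(spec: ToyComplexSpec, base_pose: Pose) -> tuple[list[np.ndarray], list[str]]:
    """k poses jittered around the base pose plus one displaced outlier."""
    rng = _rng(spec.seed, "complex")
    base = base_pose.coords()
    poses = []
    ids = []
    for i in range(spec.n_cluster_poses):
        jitter = rng.uniform(-1.0, 1.0, base.shape)
        jitter *= spec.cluster_jitter / max(np.linalg.norm(jitter, axis=1).max(), 1e-12)
        poses.append(base + jitter)
        ids.append(f"pose{i+1}")
    shift = np.array([spec.outlier_shift, 0.0, 0.0])
    poses.append(base + shift)
    ids.append(f"pose{spec.n_cluster_poses+1}")
    return poses, ids


def structure_to_pdb(model: StructureModel) -> str:
    """Serialise a StructureModel to minimal PDB text."""
    lines = []
    serial = 1
    for chain_id, residues in model.chains.items():
        for res in residues:
            for a in res.atoms:
                x, y, z = a.coord
                lines.append(
                    f"ATOM  {serial:5d} {a.name:<4s} {res.name:>3s} {chain_id}"
                    f"{res.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
                )
                serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# assay data


@dataclass(frozen=True)
class AssaySpec:
    seed: int = 0
    mode: str = "competitive"
    ki: float = 10.0  # uM
    km: float = 20.0  # uM UDP-GlcNAc
    alpha: float = 1.0
    s: float = 40.0  # uM, matches the potency-assay substrate concentration
    doses: tuple[float, ...] = DEFAULT_DOSE_GRID
    substrate_grid: tuple[float, ...] = DEFAULT_SUBSTRATE_GRID
    replicates: int = 3
    noise_cv: float = 0.05


def gen_assay_data(spec: AssaySpec) -> DoseResponse:
    """One dose-response table under the spec's mechanism and noise."""
    model = InhibitionModel(spec.mode, spec.ki, spec.km, 1.0, spec.alpha, spec.s)
    seed = int(_rng(spec.seed, "assay").integers(0, 2**31 - 1))
    return simulate_dose_response(
        doses=spec.doses, model=model, replicates=spec.replicates,
        noise_cv=spec.noise_cv, seed=seed,
    )
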