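"""Protein-ligand interaction fingerprints and a pairwise energy decomposition.

A representative docked pose is triaged by its polar contacts with the key
UDP-pocket residues (Gln839, Lys842, Thr921 by default; Asn557 can be added).
Hydrogen bonds are called geometrically: donor N/O to acceptor N/O within
3.5 A and, when the donor hydrogen is present, a donor-H-acceptor angle of at
least 120 degrees. Polar contacts use a looser 4.0 A N/O - N/O distance. A
simplified per-residue interaction energy (Coulomb + 12-6 Lennard-Jones over
atom pairs within a cutoff) ranks residue contributions; it is a geometric
pairwise surrogate for triage, not a binding free energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_align import StructureModel

#: Coulomb constant, kcal*A/(mol*e^2)
COULOMB_K = 332.0636

POLAR_ELEMENTS = ("N", "O")

#: default triage set: the key UDP-pocket residues (Methods numbering)
DEFAULT_KEY_RESIDUES = frozenset({("GLN", 839), ("LYS", 842), ("THR", 921)})

#: minimal element-based Lennard-Jones table: element -> (rmin_half A, epsilon kcal/mol)
DEFAULT_LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (0.60, 0.016),
    "C": (1.90, 0.086),
    "N": (1.85, 0.170),
    "O": (1.70, 0.210),
    "S": (2.00, 0.250),
    "P": (2.10, 0.200),
    "F": (1.65, 0.061),
    "CL": (1.99, 0.265),
    "BR": (2.13, 0.320),
}


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.5  # donor-acceptor, Angstrom
    min_dha_angle: float = 120.0  # donor-H-acceptor, degrees
    polar_contact_distance: float = 4.0  # Angstrom

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.polar_contact_distance <= 0:
            raise ValueError("distances must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle must be in (0, 180]")


@dataclass(frozen=True)
class LigandAtom:
    index: int
    element: str
    coord: tuple[float, float, float]
    charge: float = 0.0


@dataclass
class Pose:
    """A docked ligand geometry: heavy atoms plus (optionally) polar hydrogens.

    Hydrogens are associated with the nearest heavy atom within 1.3 A; a pose
    without hydrogens falls back to a distance-only hydrogen-bond criterion
    (flagged in the fingerprint).
    """

    ligand_id: str
    pose_id: str
    atoms: list[LigandAtom]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def has_hydrogens(self) -> bool:
        return any(a.element == "H" for a in self.atoms)


@dataclass(frozen=True)
class HBond:
    donor: str  # "LIG:idx" or "CHAIN/RES NUM/ATOM"
    acceptor: str
    distance: float
    angle: float | None  # None when the donor hydrogen was absent


@dataclass(frozen=True)
class ResidueContact:
    has_hbond: bool
    has_polar_contact: bool
    energy: float = 0.0


@dataclass
class ContactFingerprint:
    ligand_id: str
    pose_id: str
    residues: dict[tuple[str, int, str], ResidueContact]  # (chain, number, resname)
    distance_only: bool = False  # True when H positions were unavailable


@dataclass(frozen=True)
class TriageRule:
    required: frozenset[tuple[str, int]] = DEFAULT_KEY_RESIDUES  # (resname, number)
    mode: str = "any"

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError("required residue set must be non-empty")
        if self.mode not in ("any", "all"):
            raise ValueError("mode must be 'any' or 'all'")


# ---------------------------------------------------------------------------
# geometry helpers


def _dha_angle(donor, h, acceptor) -> float:
    """Donor-H-acceptor angle in degrees (vertex at H)."""
    v1 = np.asarray(donor, float) - np.asarray(h, float)
    v2 = np.asarray(acceptor, float) - np.asarray(h, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _attach_hydrogens(elements, coords, max_bond=1.3):
    """Map each heavy-atom index to the indices of its hydrogens."""
    coords = np.asarray(coords, float)
    h_idx = [i for i, e in enumerate(elements) if e == "H"]
    heavy_idx = [i for i, e in enumerate(elements) if e != "H"]
    attached: dict[int, list[int]] = {i: [] for i in heavy_idx}
    for h in h_idx:
        if not heavy_idx:
            break
        d = np.linalg.norm(coords[heavy_idx] - coords[h], axis=1)
        k = int(np.argmin(d))
        if d[k] <= max_bond:
            attached[heavy_idx[k]].append(h)
    return attached


def _residue_polar_sites(receptor: StructureModel):
    """Polar N/O sites and attached hydrogens, per residue."""
    sites = []
    for chain_id, res in receptor.iter_residues():
        elements = [a.element.upper() for a in res.atoms]
        coords = [a.coord for a in res.atoms]
        attached = _attach_hydrogens(elements, coords)
        for i, a in enumerate(res.atoms):
            if a.element.upper() in POLAR_ELEMENTS:
                hs = [np.asarray(coords[h], float) for h in attached.get(i, [])]
                sites.append(
                    {
                        "key": (chain_id, res.number, res.name),
                        "label": f"{chain_id}/{res.name}{res.number}/{a.name}",
                        "coord": np.asarray(a.coord, float),
                        "hydrogens": hs,
                    }
                )
    return sites


def _ligand_polar_sites(pose: Pose):
    elements = [a.element.upper() for a in pose.atoms]
    coords = [a.coord for a in pose.atoms]
    attached = _attach_hydrogens(elements, coords)
    sites = []
    for i, a in enumerate(pose.atoms):
        if a.element.upper() in POLAR_ELEMENTS:
            hs = [np.asarray(coords[h], float) for h in attached.get(i, [])]
            sites.append(
                {
                    "label": f"LIG:{a.index}",
                    "coord": np.asarray(a.coord, float),
                    "hydrogens": hs,
                }
            )
    return sites


def _hbond_between(donor_site, acceptor_site, criteria: HBondCriteria, use_angle: bool):
    d = float(np.linalg.norm(donor_site["coord"] - acceptor_site["coord"]))
    if d > criteria.max_da_distance:
        return None
    if not use_angle or not donor_site["hydrogens"]:
        return d, None
    best = max(
        _dha_angle(donor_site["coord"], h, acceptor_site["coord"])
        for h in donor_site["hydrogens"]
    )
    if best < criteria.min_dha_angle:
        return None
    return d, best


def detect_hbonds(
    pose: Pose,
    receptor: StructureModel,
    criteria: HBondCriteria | None = None,
) -> list[HBond]:
    """All ligand-protein hydrogen bonds meeting the geometric criteria.

    Both directions are scanned: ligand donor to protein acceptor and
    protein donor to ligand acceptor. A site only acts as donor when it
    carries a hydrogen; when the pose has no hydrogens at all, ligand sites
    are treated as potential donors with the angle test skipped.
    """
    criteria = criteria or HBondCriteria()
    lig_sites = _ligand_polar_sites(pose)
    rec_sites = _residue_polar_sites(receptor)
    pose_has_h = pose.has_hydrogens()
    bonds: list[HBond] = []
    for ls in lig_sites:
        for rs in rec_sites:
            # ligand donor -> protein acceptor
            if ls["hydrogens"] or not pose_has_h:
                hit = _hbond_between(ls, rs, criteria, use_angle=pose_has_h)
                if hit:
                    bonds.append(HBond(ls["label"], rs["label"], hit[0], hit[1]))
            # protein donor -> ligand acceptor
            if rs["hydrogens"]:
                hit = _hbond_between(rs, ls, criteria, use_angle=True)
                if hit:
                    bonds.append(HBond(rs["label"], ls["label"], hit[0], hit[1]))
            elif not pose_has_h:
                # fully distance-only regime for H-less receptor sites too
                hit = _hbond_between(rs, ls, criteria, use_angle=False)
                if hit:
                    bonds.append(HBond(rs["label"], ls["label"], hit[0], hit[1]))
    # deduplicate identical donor/acceptor pairs
    seen = set()
    unique = []
    for b in bonds:
        key = (b.donor, b.acceptor)
        if key not in seen:
            seen.add(key)
            unique.append(b)
    return unique


def _residue_key_of_label(label: str, receptor: StructureModel):
    if label.startswith("LIG:"):
        return None
    chain, resfull, _atom = label.split("/")
    # resfull like "LYS842"
    i = 0
    while i < len(resfull) and not (resfull[i].isdigit() or resfull[i] == "-"):
        i += 1
    return (chain, int(resfull[i:]), resfull[:i])


def contact_fingerprint(
    pose: Pose,
    receptor: StructureModel,
    criteria: HBondCriteria | None = None,
    energies: dict[tuple[str, int, str], float] | None = None,
) -> ContactFingerprint:
    """Per-residue hydrogen-bond / polar-contact flags (plus energies if given)."""
    criteria = criteria or HBondCriteria()
    bonds = detect_hbonds(pose, receptor, criteria)
    hbond_res = set()
    for b in bonds:
        for label in (b.donor, b.acceptor):
            key = _residue_key_of_label(label, receptor)
            if key is not None:
                hbond_res.add(key)
    lig_polar = np.array(
        [a.coord for a in pose.atoms if a.element.upper() in POLAR_ELEMENTS], dtype=float
    )
    residues: dict[tuple[str, int, str], ResidueContact] = {}
    for chain_id, res in receptor.iter_residues():
        key = (chain_id, res.number, res.name)
        polar = False
        if lig_polar.size:
            for a in res.atoms:
                if a.element.upper() not in POLAR_ELEMENTS:
                    continue
                d = np.linalg.norm(lig_polar - np.asarray(a.coord, float), axis=1)
                if np.any(d <= criteria.polar_contact_distance):
                    polar = True
                    break
        hb = key in hbond_res
        residues[key] = ResidueContact(
            has_hbond=hb,
            has_polar_contact=polar or hb,  # an H-bond implies a polar contact
            energy=float(energies.get(key, 0.0)) if energies else 0.0,
        )
    return ContactFingerprint(
        ligand_id=pose.ligand_id,
        pose_id=pose.pose_id,
        residues=residues,
        distance_only=not pose.has_hydrogens(),
    )


def triage_key_residues(
    fp: ContactFingerprint, rule: TriageRule | None = None
) -> tuple[bool, list[tuple[str, int]]]:
    """Apply the key-residue guideline to a fingerprint.

    Returns (pass flag, matched residues). Residues are matched by
    (residue name, number) across chains; a required residue absent from the
    receptor model is an error.
    """
    rule = rule or TriageRule()
    present = {(name, num) for (_chain, num, name) in fp.residues}
    missing = [r for r in rule.required if r not in present]
    if missing:
        raise ValueError(f"required residue(s) absent from receptor: {sorted(missing)}")
    matched = sorted(
        {
            (name, num)
            for (chain, num, name), contact in fp.residues.items()
            if (name, num) in rule.required and contact.has_polar_contact
        }
    )
    if rule.mode == "any":
        ok = len(matched) >= 1
    else:
        ok = len(matched) == len(rule.required)
    return ok, matched


# ---------------------------------------------------------------------------
# pairwise energy decomposition


def _lj_params(element: str, table: dict[str, tuple[float, float]]) -> tuple[float, float]:
    key = element.upper()
    if key not in table:
        raise ValueError(f"no Lennard-Jones parameters for element {element!r}")
    return table[key]


def pair_energy(
    qi: float, qj: float, ri: float, ei: float, rj: float, ej: float,
    r: float, dielectric: float = 1.0,
) -> float:
    """Coulomb + 12-6 LJ for one atom pair (Lorentz-Berthelot combination)."""
    coul = COULOMB_K * qi * qj / (dielectric * r)
    rmin = ri + rj
    eps = math.sqrt(ei * ej)
    frac6 = (rmin / r) ** 6
    lj = eps * (frac6 * frac6 - 2.0 * frac6)
    return coul + lj


def per_residue_energy(
    pose: Pose,
    receptor: StructureModel,
    receptor_charges: dict[tuple[str, int, str, str], float] | None = None,
    cutoff: float = 10.0,
    dielectric: float = 1.0,
    lj_table: dict[str, tuple[float, float]] | None = None,
    include_lj: bool = True,
) -> tuple[dict[tuple[str, int, str], float], float]:
    """Ligand-residue pairwise interaction energies (kcal/mol) and their total.

    For each receptor residue, sums Coulomb + 12-6 LJ over (residue atom,
    ligand atom) pairs within ``cutoff``. Ligand charges ride on the pose
    atoms; receptor charges come from ``receptor_charges`` keyed by
    (chain, residue number, residue name, atom name), default 0. LJ
    parameters are element-based from a built-in minimal table.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    table = lj_table or DEFAULT_LJ_PARAMS
    lig_xyz = pose.coords()
    lig_q = np.array([a.charge for a in pose.atoms], dtype=float)
    lig_lj = [_lj_params(a.element, table) for a in pose.atoms]
    energies: dict[tuple[str, int, str], float] = {}
    total = 0.0
    for chain_id, res in receptor.iter_residues():
        key = (chain_id, res.number, res.name)
        e_res = 0.0
        for a in res.atoms:
            q = 0.0
            if receptor_charges is not None:
                q = receptor_charges.get((chain_id, res.number, res.name, a.name), 0.0)
            rj, ej = _lj_params(a.element, table)
            d = np.linalg.norm(lig_xyz - np.asarray(a.coord, float), axis=1)
            for k in np.nonzero(d <= cutoff)[0]:
                r = float(d[k])
                if r == 0.0:
                    raise ValueError("coincident ligand/receptor atoms")
                ri, ei = lig_lj[k]
                if include_lj:
                    e_res += pair_energy(lig_q[k], q, ri, ei, rj, ej, r, dielectric)
                else:
                    e_res += COULOMB_K * lig_q[k] * q / (dielectric * r)
        energies[key] = e_res
        total += e_res
    return energies, total


def fingerprint_table(fp: ContactFingerprint) -> pd.DataFrame:
    rows = [
        {
            "ligand_id": fp.ligand_id,
            "pose_id": fp.pose_id,
            "chain": chain,
            "residue_number": num,
            "residue_name": name,
            "has_hbond": c.has_hbond,
            "has_polar": c.has_polar_contact,
            "energy_kcal_mol": c.energy,
        }
        for (chain, num, name), c in sorted(fp.residues.items())
    ]
    return pd.DataFrame(rows)
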