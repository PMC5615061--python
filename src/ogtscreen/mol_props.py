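"""Molecular graphs, physicochemical descriptors, and the lead-like filter cascade.

A compound library is screened with four rules before docking:

1. 250 <= MW <= 600 Da (average atomic masses),
2. neutral and non-zwitterionic as drawn,
3. 2 <= ring systems <= 4 (fused/spiro rings sharing an atom count once),
4. hydrogen-bond acceptors >= 1 and donors >= 2 (Lipinski-style N/O counts).

Molecules are parsed with RDKit (SMILES or SDF) into a light
:class:`MolecularGraph` container; every descriptor is then computed on that
graph so the conventions above are explicit and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import GetPeriodicTable

RDLogger.DisableLog("rdApp.*")

_PT = GetPeriodicTable()

AROMATIC = "aromatic"


class MoleculeParseError(ValueError):
    """Raised when a SMILES line or SDF block cannot be parsed."""


@dataclass(frozen=True)
class AtomRecord:
    element: str
    formal_charge: int = 0
    n_implicit_h: int = 0
    is_aromatic: bool = False


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    order: object  # 1, 2, 3 or AROMATIC


@dataclass
class MolecularGraph:
    """One library compound: atoms, bonds and formal charges as drawn."""

    id: str
    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"molecule {self.id!r}: invalid bond ({b.i},{b.j})")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"molecule {self.id!r}: duplicate bond {key}")
            seen.add(key)
        for a in self.atoms:
            if a.n_implicit_h < 0:
                raise ValueError(f"molecule {self.id!r}: negative implicit H count")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class FilterRules:
    """Thresholds of the four-rule cascade applied before docking."""

    mw_min: float = 250.0
    mw_max: float = 600.0
    require_neutral_non_zwitterion: bool = True
    ring_systems_min: int = 2
    ring_systems_max: int = 4
    hba_min: int = 1
    hbd_min: int = 2

    def __post_init__(self) -> None:
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        for name in ("ring_systems_min", "ring_systems_max", "hba_min", "hbd_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PropertyRecord:
    """Computed descriptors and per-rule outcomes for one molecule."""

    mol_id: str
    mw: float
    net_charge: int
    is_zwitterion: bool
    n_ring_systems: int
    hba: int
    hbd: int
    pass_mw: bool
    pass_charge: bool
    pass_rings: bool
    pass_hbonds: bool
    overall_pass: bool = field(default=False)

    def __post_init__(self) -> None:
        expected = self.pass_mw and self.pass_charge and self.pass_rings and self.pass_hbonds
        object.__setattr__(self, "overall_pass", expected)


# ---------------------------------------------------------------------------
# parsing


def _graph_from_rdkit(mol: Chem.Mol, mol_id: str, source: str) -> MolecularGraph:
    atoms = [
        AtomRecord(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_implicit_h=a.GetTotalNumHs(),
            is_aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.AROMATIC:
            order: object = AROMATIC
        else:
            order = int(b.GetBondTypeAsDouble())
        bonds.append(BondRecord(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(id=mol_id, atoms=atoms, bonds=bonds, source=source)


def parse_molecule(text: str, mol_id: str | None = None) -> MolecularGraph:
    """Parse one SMILES line or one SDF (molfile) block into a MolecularGraph.

    SMILES lines may carry a whitespace-separated identifier after the
    string. SDF blocks are recognised by their V2000 counts line. Atom order
    follows the input; implicit hydrogens come from the standard valence
    model.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty molecule text")
    if "V2000" in text or "V3000" in text:
        mol = Chem.MolFromMolBlock(text, sanitize=True)
        if mol is None:
            raise MoleculeParseError("malformed SDF block")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        return _graph_from_rdkit(mol, mol_id or name or "mol", source="SDF")
    fields = text.split()
    smiles = fields[0]
    inferred_id = fields[1] if len(fields) > 1 else smiles
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise MoleculeParseError(f"malformed SMILES {smiles!r}")
    return _graph_from_rdkit(mol, mol_id or inferred_id, source="SMILES")


def read_smiles_file(path) -> Iterator[MolecularGraph]:
    """Yield molecules from a SMILES file (one per line, optional id column).

    Unparseable lines are skipped (library runs should not die on one bad
    entry); callers needing strictness use :func:`parse_molecule` directly.
    """
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                yield parse_molecule(line)
            except MoleculeParseError:
                continue


def read_sdf_file(path) -> Iterator[MolecularGraph]:
    """Yield molecules from an SDF file ($$$$-delimited V2000 blocks)."""
    with open(path) as fh:
        block_lines: list[str] = []
        for line in fh:
            if line.startswith("$$$$"):
                block = "".join(block_lines)
                block_lines = []
                if block.strip():
                    try:
                        yield parse_molecule(block)
                    except MoleculeParseError:
                        continue
            else:
                block_lines.append(line)
        if "".join(block_lines).strip():
            yield parse_molecule("".join(block_lines))


def read_library(path) -> Iterator[MolecularGraph]:
    """Dispatch on extension: .sdf/.mol -> SDF, otherwise SMILES lines."""
    p = str(path)
    if p.endswith((".sdf", ".mol")):
        return read_sdf_file(path)
    return read_smiles_file(path)


# ---------------------------------------------------------------------------
# descriptors


def molecular_weight(g: MolecularGraph) -> float:
    """Molecular weight in Da using average atomic masses, hydrogens included."""
    total = 0.0
    for a in g.atoms:
        try:
            m = _PT.GetAtomicWeight(a.element)
        except Exception as exc:  # unknown element symbol
            raise ValueError(f"no atomic mass for element {a.element!r}") from exc
        if m <= 0:
            raise ValueError(f"no atomic mass for element {a.element!r}")
        total += m + a.n_implicit_h * _PT.GetAtomicWeight("H")
    return total


def _ring_bonds(g: MolecularGraph) -> list[BondRecord]:
    """Bonds lying on at least one cycle (all edges that are not bridges)."""
    G = nx.Graph()
    G.add_nodes_from(range(g.n_atoms))
    G.add_edges_from((b.i, b.j) for b in g.bonds)
    bridges = {frozenset(e) for e in nx.bridges(G)}
    return [b for b in g.bonds if frozenset((b.i, b.j)) not in bridges]


def count_ring_systems(g: MolecularGraph) -> int:
    """Number of ring systems: connected components of the ring-bond subgraph.

    Fused and spiro rings sharing at least one atom merge into one system;
    rings joined only through acyclic bonds count separately. Acyclic
    molecules give 0.
    """
    rb = _ring_bonds(g)
    if not rb:
        return 0
    H = nx.Graph()
    H.add_edges_from((b.i, b.j) for b in rb)
    return nx.number_connected_components(H)


def count_hb_donors_acceptors(
    g: MolecularGraph, exclude_pyrrole_n_from_hba: bool = False
) -> tuple[int, int]:
    """(HBD, HBA) under the Lipinski convention.

    HBD = number of N/O atoms bearing at least one hydrogen (each counted
    once regardless of H count); HBA = number of N and O atoms. Optionally
    aromatic N-H (pyrrole-type) nitrogens are excluded from the acceptor
    count.
    """
    hbd = 0
    hba = 0
    for a in g.atoms:
        if a.element not in ("N", "O"):
            continue
        has_h = a.n_implicit_h >= 1
        if has_h:
            hbd += 1
        if exclude_pyrrole_n_from_hba and a.element == "N" and a.is_aromatic and has_h:
            continue
        hba += 1
    return hbd, hba


def classify_ionization(g: MolecularGraph) -> tuple[int, bool]:
    """(net formal charge, zwitterion flag) with charges taken as drawn."""
    charges = [a.formal_charge for a in g.atoms]
    net = sum(charges)
    is_zwitterion = any(c > 0 for c in charges) and any(c < 0 for c in charges)
    return net, is_zwitterion


def apply_filter_cascade(g: MolecularGraph, rules: FilterRules | None = None) -> PropertyRecord:
    """Evaluate all four rules (no short-circuit) and record every outcome."""
    rules = rules or FilterRules()
    mw = molecular_weight(g)
    net_charge, is_zwit = classify_ionization(g)
    n_rings = count_ring_systems(g)
    hbd, hba = count_hb_donors_acceptors(g)
    pass_mw = rules.mw_min <= mw <= rules.mw_max
    pass_charge = (not rules.require_neutral_non_zwitterion) or (
        net_charge == 0 and not is_zwit
    )
    pass_rings = rules.ring_systems_min <= n_rings <= rules.ring_systems_max
    pass_hbonds = hba >= rules.hba_min and hbd >= rules.hbd_min
    return PropertyRecord(
        mol_id=g.id,
        mw=mw,
        net_charge=net_charge,
        is_zwitterion=is_zwit,
        n_ring_systems=n_rings,
        hba=hba,
        hbd=hbd,
        pass_mw=pass_mw,
        pass_charge=pass_charge,
        pass_rings=pass_rings,
        pass_hbonds=pass_hbonds,
    )


def filter_library(
    molecules: Iterable[MolecularGraph], rules: FilterRules | None = None
) -> pd.DataFrame:
    """Apply the cascade to a library; one row per molecule."""
    rules = rules or FilterRules()
    rows = [apply_filter_cascade(g, rules).__dict__ for g in molecules]
    cols = [
        "mol_id", "mw", "net_charge", "is_zwitterion", "n_ring_systems",
        "hba", "hbd", "pass_mw", "pass_charge", "pass_rings", "pass_hbonds",
        "overall_pass",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def write_filter_report(df: pd.DataFrame, path) -> None:
    out = df.rename(
        columns={
            "mol_id": "id",
            "pass_overall": "pass_overall",
            "overall_pass": "pass_overall",
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")
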