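"""Ensemble-docking consensus scoring.

Each ligand is docked against every member of a receptor ensemble (by
default the 16 human OGT crystal structures used for the UDP-pocket screen).
For every ligand x receptor pair the best (most negative) Vina affinity is
kept; the consensus score is the arithmetic mean of those per-receptor bests,
and ligands are re-ranked by ascending mean (strongest first). The top-K
prefix (default 200) goes on to pose clustering and interaction triage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the 16 OGT crystal structures forming the default receptor ensemble
DEFAULT_ENSEMBLE_IDS: tuple[str, ...] = (
    "3PE3", "3PE4", "3TAX", "4AY6", "4CDR", "4GYW", "4GYY", "4GZ3",
    "4N39", "4N3A", "4N3C", "4XI9", "4XIF", "5BNW", "5C1D", "5HGV",
)

DEFAULT_TOP_K = 200
DEFAULT_BOX_EDGE = 22.0  # Angstrom, cubic search box at the UDP pocket


@dataclass(frozen=True)
class ReceptorEnsemble:
    member_ids: tuple[str, ...] = DEFAULT_ENSEMBLE_IDS

    def __post_init__(self) -> None:
        if len(self.member_ids) == 0:
            raise ValueError("ensemble must have at least one member")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("ensemble member ids must be unique")

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class SearchBox:
    """Cubic docking search box; metadata only, no search is run here."""

    center: tuple[float, float, float]
    edges: tuple[float, float, float] = (DEFAULT_BOX_EDGE,) * 3

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.edges):
            raise ValueError("box edges must be positive")

    def contains(self, point) -> bool:
        return all(
            abs(p - c) <= e / 2.0 for p, c, e in zip(point, self.center, self.edges)
        )


@dataclass(frozen=True)
class PoseScore:
    ligand_id: str
    receptor_id: str
    pose_rank: int
    affinity: float  # kcal/mol, more negative = stronger

    def __post_init__(self) -> None:
        if self.pose_rank < 1:
            raise ValueError("pose rank is 1-based")
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")


@dataclass(frozen=True)
class ConsensusResult:
    ligand_id: str
    best_per_receptor: dict[str, float]
    mean_affinity: float
    rank: int = 0


_VINA_RESULT = re.compile(r"REMARK VINA RESULT:\s+(-?\d+(?:\.\d+)?)")


def parse_vina_result(text: str, ligand_id: str, receptor_id: str) -> list[PoseScore]:
    """Extract pose affinities from Vina PDBQT output text.

    One PoseScore per MODEL block, ranked in file order. A MODEL without a
    ``REMARK VINA RESULT`` line is an error.
    """
    scores: list[PoseScore] = []
    model_no = None
    found_result = True
    for line in text.splitlines():
        if line.startswith("MODEL"):
            if not found_result:
                raise ValueError(f"MODEL {model_no} has no VINA RESULT remark")
            parts = line.split()
            model_no = parts[1] if len(parts) > 1 else "?"
            found_result = False
        elif not found_result:
            m = _VINA_RESULT.search(line)
            if m:
                scores.append(
                    PoseScore(ligand_id, receptor_id, len(scores) + 1, float(m.group(1)))
                )
                found_result = True
    if not found_result:
        raise ValueError(f"MODEL {model_no} has no VINA RESULT remark")
    if not scores:
        raise ValueError("no MODEL with a VINA RESULT remark found")
    return scores


def make_search_box(receptor, residue: tuple[str, int], edge: float = DEFAULT_BOX_EDGE) -> SearchBox:
    """Search box centred on the centroid of a residue's side-chain atoms.

    ``residue`` is (chain id, residue number), e.g. the proline next to the
    UDP pocket, Pro559. Backbone atoms (N, CA, C, O) are excluded from the
    centroid.
    """
    backbone = {"N", "CA", "C", "O", "OXT"}
    chain_id, resnum = residue
    res = receptor.get_residue(chain_id, resnum)
    if res is None:
        raise ValueError(f"residue {chain_id}/{resnum} not found in {receptor.id}")
    side = [a.coord for a in res.atoms if a.name not in backbone]
    if not side:
        raise ValueError(f"residue {chain_id}/{resnum} has no side-chain atoms")
    center = np.mean(np.asarray(side, dtype=float), axis=0)
    return SearchBox(center=tuple(float(c) for c in center), edges=(edge,) * 3)


def scores_to_frame(scores) -> pd.DataFrame:
    """Normalise PoseScore collections / DataFrames to a long-format frame."""
    if isinstance(scores, pd.DataFrame):
        required = {"ligand_id", "receptor_id", "affinity"}
        missing = required - set(scores.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")
        return scores
    rows = [
        (s.ligand_id, s.receptor_id, s.pose_rank, s.affinity) for s in scores
    ]
    return pd.DataFrame(rows, columns=["ligand_id", "receptor_id", "pose_rank", "affinity"])


def consensus_rank(
    scores,
    ensemble: ReceptorEnsemble | None = None,
    mode: str = "strict",
) -> list[ConsensusResult]:
    """Re-rank ligands by the mean of per-receptor best affinities.

    ``strict`` mode (default) drops ligands without scores on every ensemble
    member, logging a warning; ``available`` mode averages over the members
    present. Ties in the mean are broken by ligand id, so the output order
    is deterministic and independent of input row order.
    """
    if mode not in ("strict", "available"):
        raise ValueError(f"unknown mode {mode!r}")
    ensemble = ensemble or ReceptorEnsemble()
    df = scores_to_frame(scores)
    if df.empty:
        return []
    df = df[df["receptor_id"].isin(ensemble.member_ids)]
    best = df.groupby(["ligand_id", "receptor_id"], sort=False)["affinity"].min()
    results = []
    for lig, grp in best.groupby(level=0, sort=False):
        per_receptor = {r: float(v) for (_, r), v in grp.items()}
        if mode == "strict" and len(per_receptor) < len(ensemble):
            missing = set(ensemble.member_ids) - set(per_receptor)
            logger.warning(
                "ligand %s excluded: missing scores for %d receptor(s) %s",
                lig, len(missing), sorted(missing)[:3],
            )
            continue
        results.append(
            ConsensusResult(
                ligand_id=str(lig),
                best_per_receptor=per_receptor,
                mean_affinity=float(np.mean(list(per_receptor.values()))),
            )
        )
    results.sort(key=lambda r: (r.mean_affinity, r.ligand_id))
    return [
        ConsensusResult(r.ligand_id, r.best_per_receptor, r.mean_affinity, rank=i + 1)
        for i, r in enumerate(results)
    ]


def select_top_k(ranked: list[ConsensusResult], k: int = DEFAULT_TOP_K) -> list[ConsensusResult]:
    """First min(k, n) entries of the consensus ranking."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return list(ranked[:k])


def enrichment_factor(ranked: list[ConsensusResult], active_ids: set[str], k: int) -> float:
    """EF(k) = (actives in top k / k) / (total actives / n); 1 = no enrichment."""
    n = len(ranked)
    if not 0 < k <= n:
        raise ValueError("k must be in (0, n]")
    if not active_ids:
        raise ValueError("active set is empty")
    all_ids = {r.ligand_id for r in ranked}
    if not active_ids <= all_ids:
        raise ValueError("active ids must be a subset of ranked ligand ids")
    hits = sum(1 for r in ranked[:k] if r.ligand_id in active_ids)
    return (hits / k) / (len(active_ids) / n)


def consensus_table(ranked: list[ConsensusResult], ensemble: ReceptorEnsemble | None = None) -> pd.DataFrame:
    """Wide consensus table: one row per ligand, per-receptor best columns."""
    ensemble = ensemble or ReceptorEnsemble()
    rows = []
    for r in ranked:
        row = {"ligand_id": r.ligand_id}
        for m in ensemble.member_ids:
            row[f"best_{m}"] = r.best_per_receptor.get(m, np.nan)
        row["mean_affinity"] = r.mean_affinity
        row["rank"] = r.rank
        rows.append(row)
    cols = ["ligand_id"] + [f"best_{m}" for m in ensemble.member_ids] + ["mean_affinity", "rank"]
    return pd.DataFrame(rows, columns=cols)


def read_score_table(path) -> pd.DataFrame:
    """Read a long-format TSV: ligand_id, receptor_id, pose_rank, affinity_kcal_mol."""
    df = pd.read_csv(path, sep="\t", dtype={"ligand_id": str, "receptor_id": str})
    if "affinity_kcal_mol" in df.columns:
        df = df.rename(columns={"affinity_kcal_mol": "affinity"})
    return df


def write_consensus_table(ranked, path, ensemble: ReceptorEnsemble | None = None) -> None:
    consensus_table(ranked, ensemble).to_csv(path, sep="\t", index=False, float_format="%.4f")
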