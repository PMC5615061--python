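"""End-to-end screening orchestration: filter -> rank -> cluster -> triage.

Mirrors the discovery workflow: a compound library is filtered with the
four-rule cascade, survivors are consensus-ranked over the receptor ensemble,
the top-K ligands are carried into pose clustering and key-residue triage,
and a consolidated report with stage counts is written. Every intermediate
is materialised as TSV for auditability, and a fixed configuration
reproduces byte-identical tables (timestamps live only in the run log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ensemble_screen import (
    ReceptorEnsemble,
    consensus_rank,
    select_top_k,
    read_score_table,
    write_consensus_table,
)
from .interaction_profile import (
    HBondCriteria,
    TriageRule,
    contact_fingerprint,
    triage_key_residues,
)
from .mol_props import FilterRules, filter_library, read_library, write_filter_report
from .structure_align import cluster_poses, cluster_report_rows
from .synthetic_data import (
    LibrarySpec,
    ScoreMatrixSpec,
    ToyComplexSpec,
    gen_library,
    gen_pose_cloud,
    gen_score_matrix,
    gen_toy_complex,
)
from .mol_props import parse_molecule

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "library_path", "score_path", "synthetic", "rules", "ensemble_ids",
    "top_k", "mode", "cluster_threshold", "triage_residues", "triage_mode",
    "out_dir", "seed", "log_level",
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class ScreenConfig:
    out_dir: str
    library_path: str | None = None
    score_path: str | None = None
    synthetic: dict | None = None  # {"n_molecules":..., "n_decoys":..., ...}
    rules: FilterRules = field(default_factory=FilterRules)
    ensemble_ids: tuple[str, ...] | None = None
    top_k: int = 200
    mode: str = "strict"
    cluster_threshold: float = 2.0
    triage_residues: tuple[tuple[str, int], ...] = (("GLN", 839), ("LYS", 842), ("THR", 921))
    triage_mode: str = "any"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.synthetic is None and (self.library_path is None or self.score_path is None):
            raise ConfigError("either synthetic parameters or library+score paths are required")

    def config_hash(self) -> str:
        # hash covers the scientific parameters, not output location/logging
        payload = {
            k: v for k, v in asdict(self).items()
            if k not in ("out_dir", "log_level")
        }
        payload["rules"] = asdict(self.rules)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> ScreenConfig:
    """Load and schema-validate a JSON/YAML config; unknown keys are errors."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "rules" in data and data["rules"] is not None:
        try:
            data["rules"] = FilterRules(**data["rules"])
        except TypeError as exc:
            raise ConfigError(f"bad filter rules: {exc}") from exc
    if "triage_residues" in data:
        data["triage_residues"] = tuple(
            (str(n).upper(), int(num)) for n, num in data["triage_residues"]
        )
    if "ensemble_ids" in data and data["ensemble_ids"] is not None:
        data["ensemble_ids"] = tuple(data["ensemble_ids"])
    try:
        return ScreenConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class ScreenReport:
    n_library: int
    n_filter_pass: int
    n_ranked: int
    n_top_k: int
    n_triage_pass: int
    top_k_clamped: bool
    config_hash: str
    version: str
    final_table: pd.DataFrame

    def counts(self) -> dict[str, int]:
        return {
            "library": self.n_library,
            "filter_pass": self.n_filter_pass,
            "ranked": self.n_ranked,
            "top_k": self.n_top_k,
            "triage_pass": self.n_triage_pass,
        }


def run_screen(config: ScreenConfig) -> ScreenReport:
    """Execute the full screening cascade and write all intermediates.

    Stage errors abort the run with the stage name; intermediates written
    before the failure are preserved in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("ogtscreen")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    synth = dict(config.synthetic or {})
    try:
        # ---------------- stage 1: library + filter
        try:
            if config.library_path:
                molecules = list(read_library(config.library_path))
            else:
                lib_spec = LibrarySpec(
                    seed=config.seed,
                    n_molecules=int(synth.get("n_molecules", 400)),
                )
                smiles, _truth = gen_library(lib_spec)
                molecules = [parse_molecule(line) for line in smiles]
            props = filter_library(molecules, config.rules)
            write_filter_report(props, out / "filter_report.tsv")
            passing = set(props.loc[props["overall_pass"], "mol_id"]) if len(props) else set()
            logger.info("filter: %d in, %d pass", len(props), len(passing))
        except Exception as exc:
            raise StageError("filter", exc) from exc

        # ---------------- stage 2: scores + consensus ranking
        try:
            if config.score_path:
                scores = read_score_table(config.score_path)
                scores = scores[scores["ligand_id"].isin(passing)]
            else:
                # synthetic scores cover exactly the filter survivors, so the
                # cascade counts stay monotone end to end
                survivor_ids = sorted(passing)
                n_actives = min(int(synth.get("n_actives", 10)), len(survivor_ids))
                score_spec = ScoreMatrixSpec(
                    seed=config.seed,
                    n_decoys=len(survivor_ids) - n_actives,
                    n_actives=n_actives,
                    n_receptors=int(synth.get("n_receptors", 16)),
                    poses_per_pair=int(synth.get("poses_per_pair", 3)),
                )
                scores, synth_actives = gen_score_matrix(score_spec)
                rename = dict(zip(list(scores["ligand_id"].unique()), survivor_ids))
                scores["ligand_id"] = scores["ligand_id"].map(rename)
            if config.ensemble_ids:
                ensemble = ReceptorEnsemble(tuple(config.ensemble_ids))
            else:
                receptor_ids = sorted(scores["receptor_id"].unique())
                if not receptor_ids:
                    receptor_ids = ["REC01"]
                ensemble = ReceptorEnsemble(tuple(receptor_ids))
            ranked = consensus_rank(scores, ensemble, mode=config.mode)
            write_consensus_table(ranked, out / "consensus.tsv", ensemble)
            top = select_top_k(ranked, config.top_k)
            clamped = config.top_k > len(ranked)
            pd.DataFrame(
                [(r.ligand_id, r.mean_affinity, r.rank) for r in top],
                columns=["ligand_id", "mean_affinity", "rank"],
            ).to_csv(out / "top_k.tsv", sep="\t", index=False, float_format="%.4f")
            logger.info("rank: %d ranked, top-%d -> %d", len(ranked), config.top_k, len(top))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("rank", exc) from exc

        # ---------------- stage 3: pose clustering + interaction triage
        try:
            rule = TriageRule(frozenset(config.triage_residues), config.triage_mode)
            criteria = HBondCriteria()
            cluster_rows = []
            triage_rows = []
            n_triage_pass = 0
            for i, r in enumerate(top):
                bond = (i % 3) != 2  # toy geometry: two thirds of top hits contact a key residue
                spec = ToyComplexSpec(
                    seed=config.seed + i,
                    bonded_residues=(("LYS", 842),) if bond else (),
                )
                receptor, pose, _truth = gen_toy_complex(spec)
                cloud, ids = gen_pose_cloud(spec, pose)
                pc = cluster_poses(cloud, config.cluster_threshold, ids)
                cluster_rows.extend(cluster_report_rows(r.ligand_id, pc))
                fp = contact_fingerprint(pose, receptor, criteria)
                ok, matched = triage_key_residues(fp, rule)
                n_triage_pass += bool(ok)
                triage_rows.append(
                    {
                        "ligand_id": r.ligand_id,
                        "rank": r.rank,
                        "mean_affinity": r.mean_affinity,
                        "triage_pass": ok,
                        "matched_residues": ";".join(f"{n}{num}" for n, num in matched),
                    }
                )
            pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
            final = pd.DataFrame(
                triage_rows,
                columns=["ligand_id", "rank", "mean_affinity", "triage_pass", "matched_residues"],
            )
            final.to_csv(out / "triage.tsv", sep="\t", index=False, float_format="%.4f")
            logger.info("triage: %d of %d pass", n_triage_pass, len(top))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("triage", exc) from exc

        report = ScreenReport(
            n_library=len(props),
            n_filter_pass=len(passing),
            n_ranked=len(ranked),
            n_top_k=len(top),
            n_triage_pass=n_triage_pass,
            top_k_clamped=clamped,
            config_hash=config.config_hash(),
            version=__version__,
            final_table=final,
        )
        with open(out / "report.json", "w") as fh:
            json.dump(
                {
                    "counts": report.counts(),
                    "top_k_clamped": report.top_k_clamped,
                    "config_hash": report.config_hash,
                    "version": report.version,
                },
                fh, indent=2,
            )
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
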