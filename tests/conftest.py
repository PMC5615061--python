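"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


# ---------------------------------------------------------------------------
# independent oracles


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Horn's closed-form quaternion superposition RMSD (oracle for Kabsch).

    Builds the 4x4 key matrix from the covariance of the centred point sets;
    the largest eigenvalue gives the optimal proper rotation's residual.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    M = Pc.T @ Qc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    n = P.shape[0]
    sq = (np.sum(Pc**2) + np.sum(Qc**2) - 2.0 * lam_max) / n
    return float(np.sqrt(max(sq, 0.0)))


def brute_force_consensus(table: pd.DataFrame) -> list[tuple[str, float]]:
    """Group/min/mean by hand: (ligand, mean of per-receptor best), spec order."""
    best: dict[tuple[str, str], float] = {}
    for lig, rec, aff in zip(table["ligand_id"], table["receptor_id"], table["affinity"]):
        key = (lig, rec)
        if key not in best or aff < best[key]:
            best[key] = aff
    means: dict[str, list[float]] = {}
    for (lig, _rec), aff in best.items():
        means.setdefault(lig, []).append(aff)
    out = [(lig, sum(v) / len(v)) for lig, v in means.items()]
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def brute_force_pair_energy(pose, receptor, cutoff, dielectric, lj_table, charges):
    """Flat double loop over all ligand x receptor atom pairs (no residues)."""
    from ogtscreen.interaction_profile import pair_energy, DEFAULT_LJ_PARAMS

    table = lj_table or DEFAULT_LJ_PARAMS
    total = 0.0
    for chain_id, res in receptor.iter_residues():
        for a in res.atoms:
            q = charges.get((chain_id, res.number, res.name, a.name), 0.0) if charges else 0.0
            rj, ej = table[a.element.upper()]
            for la in pose.atoms:
                ri, ei = table[la.element.upper()]
                r = float(np.linalg.norm(np.array(la.coord) - np.array(a.coord)))
                if r <= cutoff:
                    total += pair_energy(la.charge, q, ri, ei, rj, ej, r, dielectric)
    return total


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_library():
    from ogtscreen.synthetic_data import LibrarySpec, gen_library

    return gen_library(LibrarySpec(seed=7, n_molecules=200))


@pytest.fixture(scope="session")
def small_score_matrix():
    from ogtscreen.synthetic_data import ScoreMatrixSpec, gen_score_matrix

    spec = ScoreMatrixSpec(seed=3, n_decoys=300, n_actives=10, n_receptors=8, poses_per_pair=3)
    return gen_score_matrix(spec)


@pytest.fixture()
def toy_complex():
    from ogtscreen.synthetic_data import ToyComplexSpec, gen_toy_complex

    spec = ToyComplexSpec(seed=5, bonded_residues=(("LYS", 842),))
    receptor, pose, truth = gen_toy_complex(spec)
    return spec, receptor, pose, truth
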