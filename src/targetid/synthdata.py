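"""Synthetic fixtures with known ground truth for every pipeline stage.

Docking runs, MD trajectories and MM/PBSA component tables come from heavy
external software, so each stage's expected output is emulated here with a
planted, seed-deterministic truth record:

* score matrices — per-function Gaussian fitness values with one conformer
  shifted up by a chosen number of column standard deviations (the planted
  best pose); defaults mirror a 30-conformer ensemble rescored by four
  scoring functions,
* energy tables — i.i.d. Gaussian per-snapshot components around planted
  means (defaults: 100 snapshots, the cadence of sampling the last
  nanosecond every 10 ps), with a multi-site variant for a homotetramer
  carrying one ligand per binding site,
* toy trajectories — a minimal ligand/receptor system in which a hydrogen
  bond is planted in an exact, deterministic fraction of frames (defaults:
  500 frames, occupancy 0.89), plus a contact variant with per-residue
  planted contact fractions.

The module also ships verbatim transcriptions of the reference result
tables (docking validation scores, ligand docking scores, MM/PBSA
summaries) as packaged CSVs, so the aggregation code can be exercised
against published numbers without re-running any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import ScoreMatrix
from .interactions import ATOM_COLUMNS, StructureFrame, Trajectory

__all__ = [
    "DEFAULT_FUNCTIONS",
    "DEFAULT_COMPONENT_MEANS",
    "TRPV1_SITE_MEANS",
    "gen_score_matrix",
    "gen_energy_table",
    "gen_multi_site_energy_tables",
    "gen_toy_trajectory",
    "gen_contact_trajectory",
    "load_docking_validation",
    "load_nbfta_docking",
    "load_mmpbsa_summary",
    "fixture_path",
]

DEFAULT_FUNCTIONS = ("CHEMPLP", "GoldScore", "ChemScore", "ASP")

# typical scales of the four scoring functions (fitness units differ per
# function, which is exactly why consensus rescoring standardizes them)
_DEFAULT_SCORE_MEANS = (60.0, 35.0, 20.0, 30.0)
_DEFAULT_SCORE_STDS = (8.0, 6.0, 4.0, 5.0)

# explicit-solvent-like component means (kcal/mol), all five terms present
DEFAULT_COMPONENT_MEANS = {
    "VDWAALS": -35.0,
    "EEL": -7.0,
    "EPB": 34.0,
    "ENPOLAR": -27.0,
    "EDISPER": 47.0,
}

# implicit-membrane-like per-site means for a four-site homotetramer
# (EPB/EDISPER folded elsewhere, so only three components appear)
TRPV1_SITE_MEANS = {
    "LIG A": {"VDWAALS": -37.5, "EEL": 0.0, "ENPOLAR": -4.3},
    "LIG B": {"VDWAALS": -38.5, "EEL": 0.9, "ENPOLAR": -4.5},
    "LIG C": {"VDWAALS": -26.7, "EEL": -0.1, "ENPOLAR": -3.5},
    "LIG D": {"VDWAALS": -48.1, "EEL": 1.1, "ENPOLAR": -4.5},
}


# ---------------------------------------------------------------------------
# score matrices
# ---------------------------------------------------------------------------


def gen_score_matrix(
    seed: int,
    n_conformers: int = 30,
    functions: Sequence[str] = DEFAULT_FUNCTIONS,
    shift_sigma: float = 3.0,
    means: Sequence[float] | None = None,
    stds: Sequence[float] | None = None,
    best: int | None = None,
) -> tuple[ScoreMatrix, dict]:
    """Gaussian score matrix with one conformer shifted up in every column.

    Returns ``(matrix, truth)`` where ``truth["best_conformer"]`` is the id
    of the planted pose (row shifted by ``shift_sigma`` column stds).
    """
    if n_conformers < 2:
        raise ValueError("need at least 2 conformers")
    rng = np.random.default_rng(seed)
    means = list(means) if means is not None else list(_DEFAULT_SCORE_MEANS)[: len(functions)]
    stds = list(stds) if stds is not None else list(_DEFAULT_SCORE_STDS)[: len(functions)]
    if len(means) != len(functions) or len(stds) != len(functions):
        raise ValueError("means/stds must match the number of scoring functions")
    if best is None:
        best = int(rng.integers(n_conformers))
    scores = np.column_stack(
        [rng.normal(m, s, size=n_conformers) for m, s in zip(means, stds)]
    )
    scores[best] += shift_sigma * np.asarray(stds)
    ids = [f"C{i + 1:02d}" for i in range(n_conformers)]
    frame = pd.DataFrame(scores, index=ids, columns=list(functions))
    frame.index.name = "conformer_id"
    truth = {"best_conformer": ids[best], "best_index": best, "shift_sigma": shift_sigma}
    return ScoreMatrix(scores=frame), truth


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------


def gen_energy_table(
    seed: int,
    n_snapshots: int = 100,
    means: Mapping[str, float] | None = None,
    stds: Mapping[str, float] | float = 1.0,
    site_id: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-snapshot component table with Gaussian noise around planted means.

    Returns ``(table, truth)`` with ``truth["means"]`` the planted component
    means and ``truth["dg_total"]`` their implied total.
    """
    if n_snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    means = dict(means if means is not None else DEFAULT_COMPONENT_MEANS)
    if not isinstance(stds, Mapping):
        stds = {k: float(stds) for k in means}
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({"snapshot": np.arange(1, n_snapshots + 1)})
    for comp, mu in means.items():
        table[comp] = rng.normal(mu, stds.get(comp, 0.0), size=n_snapshots)
    if site_id is not None:
        table["site_id"] = site_id
    truth = {"means": means, "stds": dict(stds), "dg_total": float(sum(means.values()))}
    return table, truth


def gen_multi_site_energy_tables(
    seed: int,
    site_means: Mapping[str, Mapping[str, float]] | None = None,
    n_snapshots: int = 100,
    stds: float = 1.0,
) -> tuple[dict, dict]:
    """One energy table per binding site (defaults: the four-site pattern).

    Returns ``(tables, truth)``; ``truth["total_dg"]`` is the sum of the
    planted per-site totals.
    """
    site_means = site_means if site_means is not None else TRPV1_SITE_MEANS
    tables, site_truth = {}, {}
    for k, (site, means) in enumerate(site_means.items()):
        # distinct, reproducible child seed per site
        table, truth = gen_energy_table(
            seed * 1009 + k, n_snapshots=n_snapshots, means=means, stds=stds, site_id=site
        )
        tables[site] = table
        site_truth[site] = truth
    total = float(sum(t["dg_total"] for t in site_truth.values()))
    return tables, {"sites": site_truth, "total_dg": total}


# ---------------------------------------------------------------------------
# toy trajectories
# ---------------------------------------------------------------------------


def _atoms(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(ATOM_COLUMNS))


def gen_toy_trajectory(
    seed: int,
    n_frames: int = 500,
    occupancy: float = 0.89,
    bound_distance: float = 2.9,
    unbound_distance: float = 6.0,
) -> tuple[Trajectory, dict]:
    """Minimal ligand/receptor trajectory with an exactly planted H-bond.

    The system holds a ligand (residue ``LIG``: amide N1 with hydrogen H1
    and a carbon) plus two receptor residues (ARG 557 and GLU 570 side-chain
    tips).  In ``ceil(occupancy * n_frames)`` randomly chosen frames the
    ligand N1 sits ``bound_distance`` from GLU OE1 with H1 on the N-O axis
    (a textbook hydrogen bond); in all other frames it sits
    ``unbound_distance`` away.  The planting is deterministic given the
    seed, and the realized fraction is returned as truth.
    """
    if not (0.0 <= occupancy <= 1.0):
        raise ValueError("occupancy fraction must be in [0, 1]")
    if n_frames < 1:
        raise ValueError("need at least 1 frame")
    if not (0 < bound_distance < unbound_distance):
        raise ValueError("bound distance must be positive and below the unbound distance")
    rng = np.random.default_rng(seed)
    n_bound = ceil(occupancy * n_frames)
    bound_frames = set(rng.choice(n_frames, size=n_bound, replace=False).tolist())

    frames = []
    for k in range(n_frames):
        d = bound_distance if k in bound_frames else unbound_distance
        rows = [
            # receptor: GLU 570 side-chain carboxylate tip at the origin
            (1, "CD", "C", "GLU", 570, "A", -1.3, 0.0, 0.0, False),
            (2, "OE1", "O", "GLU", 570, "A", 0.0, 0.0, 0.0, False),
            # receptor: ARG 557 guanidinium tip, off to the side
            (3, "CZ", "C", "ARG", 557, "A", 8.0, 7.0, 0.0, False),
            (4, "NH1", "N", "ARG", 557, "A", 8.0, 8.0, 0.0, False),
            # ligand amide along +x; H1 on the N-O axis (angle 180 deg)
            (5, "N1", "N", "LIG", 900, "A", d, 0.0, 0.0, True),
            (6, "H1", "H", "LIG", 900, "A", d - 1.0, 0.0, 0.0, True),
            (7, "C1", "C", "LIG", 900, "A", d + 1.4, 0.0, 0.0, True),
        ]
        frames.append(StructureFrame(atoms=_atoms(rows), frame_index=k))

    truth = {
        "occupancy": n_bound / n_frames,
        "bound_frames": sorted(bound_frames),
        "donor": "*:LIG:*:N1",
        "acceptor": "*:GLU:570:OE1",
    }
    return Trajectory.from_frames(frames), truth


def gen_contact_trajectory(
    seed: int,
    n_frames: int = 100,
    fractions: Mapping[tuple[str, int], float] | None = None,
    contact_distance: float = 3.8,
    far_distance: float = 9.0,
) -> tuple[Trajectory, dict]:
    """Trajectory with per-residue contact fractions planted exactly.

    ``fractions`` maps ``(resname, resnum)`` to the fraction of frames in
    which that residue's single heavy atom sits ``contact_distance`` from
    the one-atom ligand (``far_distance`` otherwise).  Residues are placed
    along distinct directions so contacts never interfere.
    """
    if fractions is None:
        fractions = {("LEU", 515): 0.7, ("THR", 550): 0.2}
    rng = np.random.default_rng(seed)
    residues = list(fractions.items())
    planted = {}
    for key, frac in residues:
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"contact fraction for {key} must be in [0, 1]")
        n_contact = ceil(frac * n_frames)
        planted[key] = set(rng.choice(n_frames, size=n_contact, replace=False).tolist())

    # one unit direction per residue, well separated
    directions = []
    for i in range(len(residues)):
        angle = 2.0 * np.pi * i / max(len(residues), 1)
        directions.append(np.array([np.cos(angle), np.sin(angle), 0.0]))

    frames = []
    for k in range(n_frames):
        rows = [(1, "C1", "C", "LIG", 900, "A", 0.0, 0.0, 0.0, True)]
        for idx, ((resname, resnum), _) in enumerate(residues):
            d = contact_distance if k in planted[(resname, resnum)] else far_distance
            pos = directions[idx] * d
            rows.append(
                (idx + 2, "CA", "C", resname, resnum, "A",
                 float(pos[0]), float(pos[1]), float(pos[2]), False)
            )
        frames.append(StructureFrame(atoms=_atoms(rows), frame_index=k))

    truth = {
        key: len(chosen) / n_frames for key, chosen in planted.items()
    }
    return Trajectory.from_frames(frames), truth


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------


def fixture_path(name: str):
    """Path-like handle to a packaged fixture CSV."""
    return resources.files("targetid").joinpath("data", name)


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(fixture_path(name)) as path:
        return pd.read_csv(path)


def load_docking_validation() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Redocking validation: per-function fitness/Z rows and the printed
    consensus/RMSD summary for the three crystal-structure targets."""
    return _load("docking_validation_scores.csv"), _load("docking_validation_summary.csv")


def load_nbfta_docking() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best-pose docking scores of the query ligand against the four
    candidate targets, with the printed aggregated Z summary."""
    return _load("nbfta_docking_scores.csv"), _load("nbfta_docking_summary.csv")


def load_mmpbsa_summary() -> pd.DataFrame:
    """Published MM/PBSA component/composite means and stds per system and
    binding site (kcal/mol)."""
    frame = _load("mmpbsa_summary.csv")
    frame["site"] = frame["site"].fillna("")
    return frame
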