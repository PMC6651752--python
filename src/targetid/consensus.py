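"""Consensus rescoring of docking poses across scoring functions.

Docking scoring functions (CHEMPLP, GoldScore, ChemScore, ASP, ...) report
fitness values on incompatible scales, so raw scores cannot be summed.  Each
function's column is therefore standardized over the conformer ensemble,

    Z_ij = (S_ij - mean_j(S)) / std_j(S),

and a conformer's consensus score is the row sum ``Z_i = sum_j Z_ij``.  The
most probable binding mode is the conformer with the largest consensus score.
Selected poses are validated by heavy-atom RMSD against a reference binding
mode; the conventional redocking success criterion is RMSD < 2 Angstrom.

Standardization makes pose selection invariant to shifting a score column by
a constant or scaling it by a positive factor, which is the point: only the
relative ordering information of each function survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .tables import read_table

__all__ = [
    "ScoreMatrix",
    "ZMatrix",
    "zscore_matrix",
    "consensus_score",
    "select_pose",
    "pose_rmsd",
    "classify_pose",
]

DEFAULT_RMSD_THRESHOLD = 2.0  # Angstrom; conventional redocking success cut


@dataclass(frozen=True)
class ScoreMatrix:
    """Raw docking fitness values, conformers (rows) x scoring functions."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.shape[0] < 1 or self.scores.shape[1] < 1:
            raise ValueError("score matrix needs at least one conformer and one function")
        values = self.scores.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite score at conformer {self.scores.index[i]!r}, "
                f"function {self.scores.columns[j]!r}"
            )

    @property
    def conformer_ids(self) -> list:
        return list(self.scores.index)

    @property
    def function_ids(self) -> list:
        return list(self.scores.columns)

    @classmethod
    def read(cls, path: str | Path) -> "ScoreMatrix":
        """Read a CSV/TSV whose first column holds conformer ids."""
        frame = read_table(path)
        frame = frame.set_index(frame.columns[0])
        return cls(scores=frame.astype(float))


@dataclass(frozen=True)
class ZMatrix:
    """Standardized scores plus the per-function statistics used."""

    z: pd.DataFrame
    column_mean: pd.Series
    column_std: pd.Series

    @property
    def consensus(self) -> pd.Series:
        """Consensus score per conformer: the row sum of Z values."""
        return self.z.sum(axis=1)


def zscore_matrix(scores: ScoreMatrix, std_mode: str = "sample") -> ZMatrix:
    """Standardize each scoring-function column over the conformer ensemble.

    Parameters
    ----------
    scores:
        Raw fitness matrix.
    std_mode:
        ``"sample"`` (n-1 denominator, default) or ``"population"`` (n).
        With small conformer ensembles the choice rarely affects which pose
        wins, but it does change the printed Z values.

    A zero-variance column (all conformers scored identically, or a single
    conformer) carries no ranking information and maps to an all-zero Z
    column rather than failing.
    """
    if std_mode not in ("sample", "population"):
        raise ValueError(f"std_mode must be 'sample' or 'population', got {std_mode!r}")
    ddof = 1 if std_mode == "sample" else 0
    s = scores.scores.astype(float)
    mean = s.mean(axis=0)
    if len(s) <= ddof:
        warnings.warn(
            "standard deviation undefined for a single conformer; Z set to 0",
            stacklevel=2,
        )
        std = pd.Series(0.0, index=s.columns)
    else:
        std = s.std(axis=0, ddof=ddof)
    z = (s - mean).divide(std.replace(0.0, np.nan), axis=1).fillna(0.0)
    return ZMatrix(z=z, column_mean=mean, column_std=std)


def consensus_score(z: ZMatrix | pd.DataFrame | np.ndarray) -> pd.Series | float:
    """Sum standardized scores per conformer.

    Accepts a :class:`ZMatrix`, a Z-value DataFrame, a 2-D array (rows =
    conformers), or a single 1-D row of per-function Z values (returning a
    scalar) — the latter covers rescoring from externally reported Z rows.
    """
    if isinstance(z, ZMatrix):
        return z.consensus
    if isinstance(z, pd.DataFrame):
        return z.sum(axis=1)
    arr = np.asarray(z, dtype=float)
    if arr.ndim == 1:
        return float(arr.sum())
    return pd.Series(arr.sum(axis=1))


def select_pose(z: ZMatrix):
    """Return the conformer id with the largest consensus score.

    Ties are broken by the lowest conformer index (first occurrence), so the
    selection is deterministic.
    """
    cons = z.consensus
    if len(cons) == 0:
        raise ValueError("empty Z matrix: no conformers to select from")
    return cons.index[int(np.argmax(cons.to_numpy()))]


def _coords_and_elements(pose) -> tuple[np.ndarray, list | None]:
    """Accept an (N,3) array, a (coords, elements) pair, or a StructureFrame."""
    if hasattr(pose, "atoms"):  # StructureFrame duck type
        atoms = pose.atoms
        heavy = atoms["element"].str.upper() != "H"
        coords = atoms.loc[heavy, ["x", "y", "z"]].to_numpy(dtype=float)
        return coords, list(atoms.loc[heavy, "element"].str.upper())
    if isinstance(pose, tuple) and len(pose) == 2:
        coords, elements = pose
        return np.asarray(coords, dtype=float), list(elements)
    return np.asarray(pose, dtype=float), None


def pose_rmsd(candidate, reference, superpose: bool = False) -> float:
    """Heavy-atom RMSD between a candidate pose and a reference binding mode.

    By default the RMSD is computed in place (no superposition): docking
    poses share the receptor coordinate frame, so displacement within the
    site is part of the signal.  ``superpose=True`` performs an optimal
    rigid-body (Kabsch) fit first.  Atoms are matched by input order; no
    symmetry correction is attempted.
    """
    cand, elem_c = _coords_and_elements(candidate)
    ref, elem_r = _coords_and_elements(reference)
    if cand.shape != ref.shape:
        raise ValueError(
            f"atom count mismatch: candidate has {cand.shape[0]} atoms, "
            f"reference has {ref.shape[0]}"
        )
    if elem_c is not None and elem_r is not None and elem_c != elem_r:
        raise ValueError("element sequences differ between candidate and reference")
    if superpose:
        cand = superpose_coords(cand, ref)
    delta = cand - ref
    return float(np.sqrt(np.mean(np.sum(delta * delta, axis=1))))


def superpose_coords(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of ``mobile`` onto ``target``."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


def classify_pose(rmsd: float, threshold: float = DEFAULT_RMSD_THRESHOLD) -> str:
    """Label a redocking result: ``"reproduced"`` if RMSD < threshold."""
    return "reproduced" if rmsd < threshold else "failed"


def rescore_report(
    scores: ScoreMatrix,
    std_mode: str = "sample",
    decimals: int | None = 2,
) -> pd.DataFrame:
    """Full rescoring table: Z values, consensus and selection flag.

    ``decimals`` rounds for reporting (2 by convention); internal
    computation keeps full precision.
    """
    zm = zscore_matrix(scores, std_mode=std_mode)
    best = select_pose(zm)
    out = zm.z.copy()
    out["consensus_z"] = zm.consensus
    if decimals is not None:
        out = out.round(decimals)
    out["selected"] = [cid == best for cid in out.index]
    out.index.name = "conformer_id"
    return out.reset_index()
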