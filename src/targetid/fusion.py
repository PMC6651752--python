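"""Rank-fusion scoring for multi-method target fishing.

Ligand-based target-prediction services (e.g. similarity-ensemble or
fingerprint-nearest-neighbour methods) each return a ranked list of candidate
protein targets for a query molecule.  The lists disagree in length, scale and
content, so they are fused on ranks alone: each method's ranking is normalized
to ``(0, 1]`` (best rank -> 1), and a target's final score rewards both being
predicted by many methods and being ranked highly by each of them.

With ``M`` methods, ``F_i`` the number of methods that predict target ``i``,
and ``R_ij`` the normalized rank of target ``i`` under method ``j`` (0 when
absent), the fused score is

    S_i = (F_i / M) * (sum_j R_ij / M)            (product mode, default)
    S_i = sqrt((F_i / M) * (sum_j R_ij / M))      (geometric-mean mode)

Both factors lie in ``[0, 1]``, so ``0 < S_i <= 1`` for every emitted target
and ``S_i = 1`` exactly for a target ranked first by every method.  Because
the square root is monotone, the two modes order targets identically; the
mode only changes the score scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables import read_table

__all__ = ["PredictionTable", "normalize_ranks", "fusion_score"]

REQUIRED_COLUMNS = ("target_id", "method_id", "rank")

_AGGREGATIONS = ("product", "geometric_mean")


@dataclass(frozen=True)
class PredictionTable:
    """Ranked target predictions pooled from one or more methods.

    Parameters
    ----------
    frame:
        Tidy table with columns ``target_id``, ``method_id`` and ``rank``
        (1 = best).  A ``normalized_rank`` column is attached by
        :func:`normalize_ranks`.
    methods:
        The full set of method ids, which may be wider than the set observed
        in ``frame`` (a method that returned an empty list still counts
        toward ``M``).
    """

    frame: pd.DataFrame
    methods: frozenset

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"prediction table is missing columns {missing}")
        if len(self.frame) == 0:
            raise ValueError("prediction table has no entries")
        if not self.methods:
            raise ValueError("prediction table declares no methods (M must be >= 1)")
        unknown = set(self.frame["method_id"]) - set(self.methods)
        if unknown:
            raise ValueError(f"entries reference undeclared methods: {sorted(unknown)}")
        ranks = self.frame["rank"]
        if not np.issubdtype(np.asarray(ranks).dtype, np.integer):
            if not np.all(np.asarray(ranks, dtype=float) == np.asarray(ranks, dtype=float).astype(int)):
                raise ValueError("ranks must be positive integers")
        if (np.asarray(ranks, dtype=float) < 1).any():
            raise ValueError("ranks must be positive integers (>= 1)")
        for method, sub in self.frame.groupby("method_id", sort=False):
            r = np.sort(np.asarray(sub["rank"], dtype=int))
            if len(np.unique(r)) != len(r):
                raise ValueError(f"duplicate rank within method {method!r}")
            # a returned list is ranked contiguously from 1
            if r[0] != 1 or r[-1] != len(r):
                raise ValueError(
                    f"method {method!r} ranks must be exactly 1..{len(r)}, got {r.tolist()}"
                )
            if sub["target_id"].duplicated().any():
                raise ValueError(f"method {method!r} lists a target more than once")

    @property
    def n_methods(self) -> int:
        return len(self.methods)

    @classmethod
    def from_records(
        cls,
        entries: Iterable[tuple],
        methods: Sequence | None = None,
    ) -> "PredictionTable":
        """Build from ``(target_id, method_id, rank)`` triples."""
        frame = pd.DataFrame(list(entries), columns=list(REQUIRED_COLUMNS))
        if methods is None:
            methods = frame["method_id"].unique()
        return cls(frame=frame, methods=frozenset(methods))

    @classmethod
    def read(cls, path: str | Path, methods: Sequence | None = None) -> "PredictionTable":
        """Read a CSV/TSV with columns target_id, method_id, rank."""
        frame = read_table(path, required=REQUIRED_COLUMNS, numeric=("rank",))
        frame["rank"] = frame["rank"].astype(int)
        if methods is None:
            methods = frame["method_id"].unique()
        return cls(frame=frame, methods=frozenset(methods))


def normalize_ranks(table: PredictionTable) -> PredictionTable:
    """Attach normalized ranks ``R_ij = (N_j - rank + 1) / N_j``.

    ``N_j`` is the number of targets method ``j`` returned, so the best rank
    maps to 1.0 and the worst to ``1/N_j``; targets a method did not return
    implicitly contribute ``R_ij = 0`` during fusion.
    """
    frame = table.frame.copy()
    n_per_method = frame.groupby("method_id")["target_id"].transform("size")
    frame["normalized_rank"] = (n_per_method - frame["rank"] + 1) / n_per_method
    return PredictionTable(frame=frame, methods=table.methods)


def fusion_score(
    table: PredictionTable,
    aggregation: str = "product",
) -> pd.DataFrame:
    """Fuse per-method rankings into one score per target.

    Parameters
    ----------
    table:
        Prediction table; normalized ranks are computed if absent.
    aggregation:
        ``"product"`` (the default) scores ``(F_i/M) * (mean_j R_ij)``;
        ``"geometric_mean"`` takes the square root of that product.  The two
        modes induce the same target ordering.

    Returns
    -------
    DataFrame with columns ``target_id``, ``frequency``,
    ``mean_normalized_rank``, ``score`` and ``rank``, sorted by descending
    score with ties broken lexicographically by target id.
    """
    if aggregation not in _AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {_AGGREGATIONS}, got {aggregation!r}")
    if "normalized_rank" not in table.frame.columns:
        table = normalize_ranks(table)
    m = table.n_methods

    grouped = table.frame.groupby("target_id", sort=False)
    freq = grouped["method_id"].nunique()
    # absent methods contribute R_ij = 0, so the mean divides by M, not F_i
    mean_norm = grouped["normalized_rank"].sum() / m

    score = (freq / m) * mean_norm
    if aggregation == "geometric_mean":
        score = np.sqrt(score)

    out = pd.DataFrame(
        {
            "target_id": freq.index,
            "frequency": freq.to_numpy(),
            "mean_normalized_rank": mean_norm.to_numpy(),
            "score": np.asarray(score, dtype=float),
        }
    )
    out = out.sort_values(
        ["score", "target_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
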