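"""Aggregation of per-snapshot MM/PBSA energy components.

End-point MM/PBSA binding free energies are averages over MD snapshots of a
molecular-mechanics gas-phase term and a Poisson-Boltzmann solvation term.
This module consumes the per-snapshot component tables produced by external
tools (Amber-style column names) and aggregates them:

    dG_gas   = VDWAALS + EEL            (+ any 1-4 sub-terms present)
    dG_solv  = EPB + ENPOLAR + EDISPER
    dG_total = dG_gas + dG_solv

computed per snapshot *before* averaging, so the composite means satisfy
``mean(dG_total) = mean(dG_gas) + mean(dG_solv)`` exactly.  All energies are
kcal/mol.  Components absent from an input (e.g. EPB/EDISPER in an
implicit-membrane run that folds them elsewhere) contribute exactly zero.

A receptor with several equivalent binding sites (a homotetramer with one
ligand per site) is handled by summing per-site totals; the uncertainty of
the multi-site sum is combined in quadrature when only summaries exist, or
recomputed from synchronized per-snapshot sums when the full tables are
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import read_table

__all__ = [
    "GAS_COMPONENTS",
    "SOLV_COMPONENTS",
    "EnergySummary",
    "composite_energies",
    "summary_from_means",
    "multi_site_total",
    "favorability",
    "favorability_report",
]

GAS_COMPONENTS = ("VDWAALS", "EEL", "1-4 VDW", "1-4 EEL")
SOLV_COMPONENTS = ("EPB", "ENPOLAR", "EDISPER")
COMPOSITES = ("DG_GAS", "DG_SOLV", "DG_TOTAL")


@dataclass(frozen=True)
class EnergySummary:
    """Mean/std of each component and composite for one complex or site.

    ``stats`` is indexed by component name with columns ``mean`` and ``std``;
    ``per_snapshot`` retains the snapshot-level composites when they were
    available, enabling synchronized multi-site sums.
    """

    stats: pd.DataFrame
    n_snapshots: int
    site_id: str | None = None
    per_snapshot: pd.DataFrame | None = None

    @property
    def dg_total(self) -> float:
        return float(self.stats.loc["DG_TOTAL", "mean"])

    @property
    def dg_total_std(self) -> float:
        return float(self.stats.loc["DG_TOTAL", "std"])


def _validated(table: pd.DataFrame) -> pd.DataFrame:
    if len(table) == 0:
        raise ValueError("energy table has zero snapshots")
    known = [c for c in GAS_COMPONENTS + SOLV_COMPONENTS if c in table.columns]
    if not known:
        raise ValueError(
            f"energy table has none of the recognized components "
            f"{GAS_COMPONENTS + SOLV_COMPONENTS}"
        )
    values = table[known].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("energy table contains non-finite component values")
    return table


def read_energy_table(path: str | Path) -> pd.DataFrame:
    """Read a per-snapshot component CSV/TSV (Amber-style column names)."""
    frame = read_table(path)
    numeric = [c for c in GAS_COMPONENTS + SOLV_COMPONENTS if c in frame.columns]
    for col in numeric:
        frame[col] = pd.to_numeric(frame[col])
    return _validated(frame)


def composite_energies(table: pd.DataFrame, site_id: str | None = None) -> EnergySummary:
    """Aggregate a per-snapshot component table into means and sample stds.

    Composites are formed per snapshot, then summarized; with a single
    snapshot the sample std is undefined and reported as 0.
    """
    table = _validated(table)

    def col(name: str) -> np.ndarray:
        if name in table.columns:
            return table[name].to_numpy(dtype=float)
        return np.zeros(len(table))

    per = pd.DataFrame(index=table.index)
    for name in GAS_COMPONENTS + SOLV_COMPONENTS:
        if name in table.columns:
            per[name] = col(name)
    per["DG_GAS"] = sum(col(c) for c in GAS_COMPONENTS)
    per["DG_SOLV"] = sum(col(c) for c in SOLV_COMPONENTS)
    per["DG_TOTAL"] = per["DG_GAS"] + per["DG_SOLV"]

    std = per.std(ddof=1).fillna(0.0) if len(per) > 1 else pd.Series(0.0, index=per.columns)
    stats = pd.DataFrame({"mean": per.mean(), "std": std})
    return EnergySummary(
        stats=stats, n_snapshots=len(table), site_id=site_id, per_snapshot=per
    )


def summary_from_means(
    means: Mapping[str, float],
    stds: Mapping[str, float] | None = None,
    site_id: str | None = None,
    n_snapshots: int = 0,
) -> EnergySummary:
    """Build a summary from reported means/stds (no snapshot data).

    Composite means absent from ``means`` are recomputed from the parts
    (missing components count as zero); composite stds cannot be recovered
    from component stds without the snapshot covariances and are left NaN
    unless supplied.
    """
    means = dict(means)
    stds = dict(stds or {})
    means.setdefault("DG_GAS", sum(means.get(c, 0.0) for c in GAS_COMPONENTS))
    means.setdefault("DG_SOLV", sum(means.get(c, 0.0) for c in SOLV_COMPONENTS))
    means.setdefault("DG_TOTAL", means["DG_GAS"] + means["DG_SOLV"])
    index = [k for k in list(dict.fromkeys(list(means)))]
    stats = pd.DataFrame(
        {
            "mean": [means[k] for k in index],
            "std": [stds.get(k, np.nan) for k in index],
        },
        index=index,
    )
    return EnergySummary(stats=stats, n_snapshots=n_snapshots, site_id=site_id)


def multi_site_total(
    summaries: Sequence[EnergySummary],
    mode: str = "quadrature",
) -> tuple[float, float]:
    """Total binding free energy over several occupied binding sites.

    Returns ``(mean, std)`` of the summed ``dG_total``.

    mode:
        ``"quadrature"`` combines per-site stds as sqrt(sum of squares),
        assuming independent sites; ``"per-snapshot"`` requires snapshot
        tables of equal length and recomputes the std of the synchronized
        per-snapshot sum (capturing inter-site correlation).
    """
    if not summaries:
        raise ValueError("multi_site_total needs at least one site summary")
    total_mean = float(sum(s.dg_total for s in summaries))
    if mode == "per-snapshot":
        if any(s.per_snapshot is None for s in summaries):
            raise ValueError("per-snapshot mode requires snapshot-level tables for every site")
        lengths = {len(s.per_snapshot) for s in summaries}
        if len(lengths) != 1:
            raise ValueError(f"sites have differing snapshot counts: {sorted(lengths)}")
        summed = sum(s.per_snapshot["DG_TOTAL"].to_numpy() for s in summaries)
        std = float(np.std(summed, ddof=1)) if len(summed) > 1 else 0.0
        return total_mean, std
    if mode != "quadrature":
        raise ValueError(f"mode must be 'quadrature' or 'per-snapshot', got {mode!r}")
    stds = np.array([s.dg_total_std for s in summaries], dtype=float)
    if np.isnan(stds).any():
        warnings.warn("missing per-site stds; combined std is NaN", stacklevel=2)
    if len(summaries) > 1:
        warnings.warn(
            "quadrature combination assumes independent binding sites", stacklevel=2
        )
    return total_mean, float(np.sqrt(np.sum(stds**2)))


def favorability(dg_total: float) -> str:
    """Classify a binding free energy: negative is favorable."""
    return "favorable" if dg_total < 0 else "unfavorable"


def favorability_report(summaries: Mapping[str, EnergySummary]) -> pd.DataFrame:
    """Tabulate dG_total and its favorability per target/site."""
    rows = []
    for name, summary in summaries.items():
        rows.append(
            {
                "system": name,
                "dg_total": summary.dg_total,
                "std": summary.dg_total_std if "DG_TOTAL" in summary.stats.index else np.nan,
                "classification": favorability(summary.dg_total),
            }
        )
    return pd.DataFrame(rows)


def summary_table(summary: EnergySummary, decimals: int = 2) -> pd.DataFrame:
    """Report-ready component/composite table, rounded to ``decimals``."""
    out = summary.stats.round(decimals)
    out.index.name = "component"
    return out.reset_index()
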