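"""Pipeline configuration and stage orchestration.

The computational target-identification workflow runs in a fixed order —
target fishing (rank fusion), consensus docking rescoring, MM/PBSA energy
aggregation, MD interaction analysis — with each stage consuming tables or
structures produced upstream (here: by external docking/MD tools or the
synthetic generators).  ``run_pipeline`` executes any subset of stages from a
validated config and writes one CSV per stage plus a combined summary, each
stamped with a provenance header (tool version, config hash, input
checksums).

The special ``fixtures`` stage recomputes the headline numbers of the
packaged reference tables (consensus Z sums, composite free-energy identity,
four-site total) without external inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .consensus import ScoreMatrix, consensus_score, rescore_report
from .energetics import (
    composite_energies,
    favorability_report,
    multi_site_total,
    read_energy_table,
    summary_from_means,
    summary_table,
)
from .fusion import PredictionTable, fusion_score
from .interactions import ligand_rmsd_series, load_criteria, occupancy
from .pdbio import read_pdb, read_trajectory
from .synthdata import load_docking_validation, load_mmpbsa_summary, load_nbfta_docking
from .tables import provenance_header, write_table

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("targetid")

STAGE_ORDER = ("fusion", "consensus", "energetics", "interactions", "fixtures")


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")

    stages: list[str] = Field(default_factory=list)
    outdir: Path = Path("results")
    seed: int = 0
    log_level: str = "INFO"

    # fusion
    predictions: Optional[Path] = None
    aggregation: str = "product"

    # consensus
    scores: Optional[Path] = None
    std_mode: str = "sample"

    # energetics
    energy_tables: list[Path] = Field(default_factory=list)
    multi_site_mode: str = "per-snapshot"

    # interactions
    trajectory: Optional[Path] = None
    criteria: Optional[Path] = None
    reference: Optional[Path] = None
    superpose: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig, inputs=()) -> dict:
    return provenance_header(__version__, config.config_hash(), inputs)


def _stage_fusion(config: PipelineConfig) -> pd.DataFrame:
    if config.predictions is None:
        raise ValueError("fusion stage requires 'predictions' input path")
    table = PredictionTable.read(config.predictions)
    return fusion_score(table, aggregation=config.aggregation)


def _stage_consensus(config: PipelineConfig) -> pd.DataFrame:
    if config.scores is None:
        raise ValueError("consensus stage requires 'scores' input path")
    matrix = ScoreMatrix.read(config.scores)
    return rescore_report(matrix, std_mode=config.std_mode)


def _stage_energetics(config: PipelineConfig) -> pd.DataFrame:
    if not config.energy_tables:
        raise ValueError("energetics stage requires 'energy_tables' input paths")
    summaries = {}
    for path in config.energy_tables:
        table = read_energy_table(path)
        site = str(table["site_id"].iloc[0]) if "site_id" in table.columns else Path(path).stem
        summaries[site] = composite_energies(table, site_id=site)
    frames = []
    for site, summary in summaries.items():
        block = summary_table(summary)
        block.insert(0, "site", site)
        frames.append(block)
    report = pd.concat(frames, ignore_index=True)
    if len(summaries) > 1:
        total_mean, total_std = multi_site_total(
            list(summaries.values()), mode=config.multi_site_mode
        )
        report = pd.concat(
            [
                report,
                pd.DataFrame(
                    [{"site": "ALL", "component": "DG_TOTAL",
                      "mean": round(total_mean, 2), "std": round(total_std, 2)}]
                ),
            ],
            ignore_index=True,
        )
    fav = favorability_report(summaries)
    fav = fav.rename(columns={"system": "site", "dg_total": "mean"})
    fav["component"] = "CLASSIFICATION"
    report = pd.concat([report, fav[["site", "component", "classification"]]], ignore_index=True)
    return report


def _stage_interactions(config: PipelineConfig) -> pd.DataFrame:
    if config.trajectory is None:
        raise ValueError("interactions stage requires 'trajectory' input path")
    traj = read_trajectory(config.trajectory)
    rows = []
    if config.criteria is not None:
        for criterion in load_criteria(config.criteria):
            report = occupancy(traj, criterion)
            rows.append(
                {
                    "analysis": "occupancy",
                    "label": report.label,
                    "value": report.frequency,
                    "n_frames": report.total_frames,
                }
            )
    if config.reference is not None:
        reference = read_pdb(config.reference)
        series = ligand_rmsd_series(traj, reference, superpose_backbone=config.superpose)
        rows.append(
            {
                "analysis": "ligand_rmsd_mean",
                "label": "vs_reference",
                "value": float(series.mean()),
                "n_frames": len(series),
            }
        )
    if not rows:
        raise ValueError("interactions stage needs 'criteria' and/or 'reference'")
    return pd.DataFrame(rows)


def _stage_fixtures(config: PipelineConfig) -> pd.DataFrame:
    """Recompute headline quantities from the packaged reference tables."""
    rows = []
    val_scores, _ = load_docking_validation()
    for target, sub in val_scores.groupby("target", sort=False):
        rows.append(
            {
                "quantity": f"consensus_z[{target}]",
                "value": round(float(consensus_score(sub["z_score"].to_numpy())), 2),
            }
        )
    lig_scores, _ = load_nbfta_docking()
    for target, sub in lig_scores.groupby("target", sort=False):
        rows.append(
            {
                "quantity": f"aggregated_z[{target}]",
                "value": round(float(consensus_score(sub["z_score"].to_numpy())), 2),
            }
        )
    mmpbsa = load_mmpbsa_summary()
    site_totals = []
    for (system, site), sub in mmpbsa.groupby(["system", "site"], sort=False):
        means = dict(zip(sub["component"], sub["mean"]))
        stds = dict(zip(sub["component"], sub["std"]))
        gas, solv = means.get("DG_GAS"), means.get("DG_SOLV")
        if gas is not None and solv is not None:
            summary = summary_from_means(
                {k: v for k, v in means.items() if k not in ("DG_TOTAL",)}, stds
            )
            label = f"{system}:{site}" if site else system
            rows.append(
                {"quantity": f"dg_total[{label}]", "value": round(summary.dg_total, 2)}
            )
            if site.startswith("LIG"):
                site_totals.append(
                    summary_from_means(means, stds, site_id=site)
                )
    if site_totals:
        total_mean, total_std = multi_site_total(site_totals, mode="quadrature")
        rows.append({"quantity": "dg_total[four_sites]", "value": round(total_mean, 2)})
        rows.append({"quantity": "dg_total_std[four_sites]", "value": round(total_std, 2)})
    return pd.DataFrame(rows)


_STAGE_FUNCS = {
    "fusion": _stage_fusion,
    "consensus": _stage_consensus,
    "energetics": _stage_energetics,
    "interactions": _stage_interactions,
    "fixtures": _stage_fixtures,
}


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the requested stages in workflow order.

    Returns a mapping of stage name to its output CSV path.  An empty stage
    list is a no-op.  Any stage failure raises with the stage named.
    """
    logging.basicConfig(level=config.log_level)
    unknown = [s for s in config.stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid: {list(STAGE_ORDER)}")
    ordered = [s for s in STAGE_ORDER if s in config.stages]
    outputs: dict[str, Path] = {}
    inputs = [
        p
        for p in [config.predictions, config.scores, config.trajectory,
                  config.reference, config.criteria, *config.energy_tables]
        if p is not None
    ]
    for stage in ordered:
        t0 = time.perf_counter()
        try:
            result = _STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        out = Path(config.outdir) / f"{stage}.csv"
        write_table(result, out, provenance=_provenance(config, inputs))
        outputs[stage] = out
        log.info("stage %s finished in %.2fs -> %s", stage, time.perf_counter() - t0, out)
    if outputs:
        summary = pd.DataFrame(
            [{"stage": s, "output": str(p)} for s, p in outputs.items()]
        )
        write_table(summary, Path(config.outdir) / "summary.csv",
                    provenance=_provenance(config, inputs))
    return outputs
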