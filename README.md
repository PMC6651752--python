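# targetid

Consensus computational target identification for small molecules: the
post-processing half of a structure-based target-fishing campaign, packaged
as a tested Python library with a thin command-line interface.

Given a bioactive compound, identifying *what it binds* typically chains four
computational stages, each producing tables or structures that need careful
statistical aggregation:

1. **Rank-fusion target fishing** (`targetid.fusion`). Several ligand-based
   prediction services each return a ranked list of candidate protein
   targets. With `M` methods, `F_i` the number of methods predicting target
   `i`, and `R_ij = (N_j − rank + 1)/N_j` the normalized rank of target `i`
   under method `j` (0 when absent, 1 for the best rank), the fused score is

   `S_i = (F_i/M) · (Σ_j R_ij / M)`

   (optionally its square root, the geometric mean of the two factors — both
   modes order targets identically). `S_i ∈ (0, 1]`, with 1 reserved for a
   target ranked first by every method.

2. **Consensus docking rescoring** (`targetid.consensus`). Docking scoring
   functions (CHEMPLP, GoldScore, ChemScore, ASP, …) report fitness on
   incompatible scales. Each function's column is standardized over the
   conformer ensemble, `Z_ij = (S_ij − S̄_j)/std(S_j)`, and the pose with the
   largest consensus score `Z_i = Σ_j Z_ij` is selected as the most probable
   binding mode. Poses are validated by heavy-atom RMSD against a reference
   binding mode (redocking succeeds below 2 Å by convention).

3. **MM/PBSA aggregation** (`targetid.energetics`). Per-snapshot energy
   components from end-point free-energy calculations are combined per
   snapshot — `ΔG_gas = VDWAALS + EEL`, `ΔG_solv = EPB + ENPOLAR + EDISPER`,
   `ΔG_total = ΔG_gas + ΔG_solv` — then summarized as mean ± std (kcal/mol).
   Multi-site receptors (e.g. a homotetramer with one ligand per binding
   site) get site sums with quadrature or synchronized per-snapshot errors.

4. **MD interaction analysis** (`targetid.interactions`). Hydrogen bonds
   (donor–acceptor ≤ 3.5 Å, D–H···A ≥ 120° when hydrogens are present),
   residue contacts (heavy-atom ≤ 4.5 Å), metal-coordination distances
   (e.g. carbonyl O–Zn²⁺ < 2.6 Å), interaction occupancies over snapshot
   ensembles, per-frame ligand RMSD against the docked pose, and
   ligand–residue contact networks weighted by frequency.

Because the upstream tools (docking engines, MD packages, PB solvers, web
services) are external, `targetid.synthdata` generates every input with
planted, seed-deterministic ground truth — score matrices with a known best
conformer, Gaussian energy tables with known means, toy trajectories with an
exact planted hydrogen-bond occupancy — and also ships transcriptions of
published reference result tables so the aggregation arithmetic can be
checked against printed values.

## Worked example

```python
from targetid import PredictionTable, fusion_score

entries = [
    ("MMP1", "moltarpred", 1), ("TRPV1", "moltarpred", 2), ("HDAC1", "moltarpred", 3),
    ("MMP1", "charite", 1), ("MMP2", "charite", 2),
    ("TRPV1", "sea", 1), ("MMP1", "sea", 2), ("MMP9", "sea", 3),
]
table = PredictionTable.from_records(entries, methods=["moltarpred", "charite", "sea"])
print(fusion_score(table, aggregation="product").to_string(index=False))
```

prints

```
target_id  frequency  mean_normalized_rank    score  rank
     MMP1          3              0.888889 0.888889     1
    TRPV1          2              0.555556 0.370370     2
     MMP2          1              0.166667 0.055556     3
    HDAC1          1              0.111111 0.037037     4
     MMP9          1              0.111111 0.037037     5
```

MMP1 leads: all three methods predict it, twice at rank 1 (`F_i/M = 1`,
mean normalized rank 0.89). Targets seen by one method cannot exceed
`(1/3)·(1/3) ≈ 0.11`. The `examples/` directory has one narrative script per
capability (fusion, rescoring, energy aggregation, trajectory analysis);
each prints the numbers it computes and what they mean.

The same operations are available from the shell:

```sh
targetid fuse-targets --in preds.tsv --aggregation product --out fused.csv
targetid consensus-rescore --scores scores.csv --std-mode sample --out z.csv
targetid mmpbsa-aggregate --in lig_a.csv --in lig_b.csv --mode per-snapshot --out dg.csv
targetid md-occupancy --traj traj.pdb --criteria criteria.yaml --out occ.csv
targetid synth traj --seed 1 --frames 500 --occupancy 0.89 --out traj.pdb
targetid run --config pipeline.yaml
```

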