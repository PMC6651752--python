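# Methods

This note documents the models and procedures implemented in `targetid`,
the defaults chosen where the underlying methods admit more than one
convention, and what the synthetic benchmarks do and do not demonstrate.

## Rank fusion for target fishing

Target-prediction methods return ranked lists of unequal length and
incomparable score scales, so fusion uses ranks only. For method `j`
returning `N_j` targets, the normalized rank of target `i` is
`R_ij = (N_j − rank_ij + 1)/N_j`: the top hit gets 1, the last hit `1/N_j`,
and a target the method did not return contributes 0. Ranks within a method
must be exactly `1..N_j` — a returned list is ranked contiguously, and
enforcing this keeps `R_ij ∈ (0, 1]`.

The fused score multiplies the prediction frequency `F_i/M` by the mean
normalized rank `Σ_j R_ij / M` (the sum runs over all `M` methods, absences
contributing zero, so both factors live in `[0, 1]`). Two aggregation modes
are provided: the plain product (default) and its square root, the geometric
mean of the two factors. Since `√x` is strictly monotone on `[0, 1]`, the
modes produce identical target orderings — only the score scale differs —
and the test suite asserts this on randomized tables. Ties are broken
lexicographically by target id so output is deterministic. `M` is a free
parameter (the motivating use case has three methods, but nothing depends
on that). Method scores, where available, are deliberately ignored: the
fusion is defined on rankings.

## Consensus Z-score rescoring

Raw docking fitness values from different scoring functions are standardized
per function over the conformer ensemble: `Z_ij = (S_ij − S̄_j)/std(S_j)`.
The consensus score of a conformer is the row sum, and the pose with the
largest consensus is selected (ties: lowest conformer index).

Numerical conventions:

* **Sample vs population std.** The denominator convention is not fixed by
  the method definition. Default is the sample std (`n−1`), the usual choice
  for a ~30-conformer ensemble; population std is available via
  `std_mode="population"`. Selection order is rarely affected, but printed Z
  values change, so the flag is explicit.
* **Degenerate columns.** A zero-variance column (or a single conformer)
  carries no ranking information; its Z column is set to 0 rather than
  failing, making a degenerate scoring function neutral. A single-conformer
  matrix warns.
* **Invariance.** Standardization makes the Z matrix — hence pose
  selection — invariant to shifting a score column by a constant or scaling
  it by a positive factor. This is tested property-style.
* **Reporting** rounds to two decimals; all internal arithmetic is full
  precision.

Pose validation uses heavy-atom RMSD with atoms matched by input order and
**no superposition by default**: docking poses share the receptor frame, so
in-place deviation is the quantity of interest. A Kabsch fit
(`superpose=True`, via `scipy.spatial.transform.Rotation.align_vectors`) is
available when frames differ. No symmetry-corrected (automorphism-aware)
RMSD is attempted — a known limitation for ligands with topologically
equivalent atoms. The conventional redocking success threshold of 2 Å is the
default of `classify_pose` and configurable.

## MM/PBSA aggregation

Composites are formed **per snapshot** — `ΔG_gas = VDWAALS + EEL` (folding
in 1–4 sub-terms when a table carries them, per Amber output convention),
`ΔG_solv = EPB + ENPOLAR + EDISPER`, `ΔG_total` their sum — then averaged,
so the composite means satisfy the additive identity exactly (asserted to
1e-9). Components absent from a table contribute exactly zero; this is the
correct reading of implicit-membrane runs whose published summaries leave
EPB/EDISPER blank, where the printed `ΔG_solv` equals the ENPOLAR row.
Sample (`n−1`) stds match common MM/PBSA tooling; a single snapshot reports
std 0.

Multi-site totals sum the per-site `ΔG_total` means. For the uncertainty,
two modes exist because the right answer depends on what data survive:
with per-snapshot tables, the std of the synchronized per-snapshot sum is
self-consistent and captures inter-site correlation (the default in the
pipeline); with summary-only input, stds combine in quadrature under an
explicit independence warning. On the packaged reference summaries the
quadrature std is 5.52 kcal/mol where the source prints 5.55 — consistent
with the source having used the snapshot-wise route, which its published
summary tables no longer allow recomputing.

The transcribed reference tables contain a few 0.01 internal
inconsistencies (independent rounding of gas, solv and total from full
precision); tests on transcribed values therefore allow one rounding unit,
while the package's own arithmetic is held to 1e-9.

Favorability is classified by sign: `ΔG_total < 0` favorable, `≥ 0`
unfavorable (boundary inclusive on the unfavorable side).

## Interaction geometry and occupancy

The source analyses state outcomes (an interaction present in some fraction
of snapshots) without geometric definitions, so standard MD-analysis
criteria are adopted and exposed as configurable parameters:

* **Hydrogen bond:** donor–acceptor heavy-atom distance ≤ 3.5 Å, plus
  D–H···A angle ≥ 120° whenever a hydrogen is covalently attached to the
  donor (attachment = same residue, ≤ 1.25 Å). Models without hydrogens
  fall back to the distance test alone.
* **Contact:** any heavy-atom pair ≤ 4.5 Å links two residues; cross-chain
  contacts are supported (binding sites at subunit interfaces need them).
* **Metal coordination:** minimum selected-ligand-atom distance to a single
  matched metal ion, coordinating iff strictly below 2.6 Å.
* **Residue-pair hydrogen bonds** (e.g. an ARG guanidinium N to a GLU
  carboxylate O) reuse the hydrogen-bond criterion with receptor selectors;
  a "non-hydrogen-bond interaction" is a contact that fails the
  hydrogen-bond test.

Occupancy is the exact satisfied-frame fraction, invariant to frame order;
per-chain grouping specializes both selectors to each chain, the natural
per-binding-site analysis for a homotetramer. Ligand RMSD series are
in-place per frame against a reference pose (typically the initial docking
structure), with optional receptor-backbone (N, CA, C, O) superposition to
remove global drift; a stability contract flags a series whose trailing
window std falls below a configurable threshold. The interaction network
weights ligand–residue edges by contact frequency and emits a sorted edge
list.

Atom selection uses a four-field glob grammar
`chain:resname:resnum:atomname` (each field an `fnmatch` pattern; missing
trailing fields default to `*`). Distances are computed with dense
all-pairs arithmetic — exact, and fast at binding-site scale (hundreds of
atoms, hundreds of frames); the unit tests verify the detectors against
plain-loop oracles on randomized frames.

Structures travel as PDB / multi-model PDB only; other trajectory formats
are expected to be converted upstream. Coordinates are Å, energies
kcal/mol, throughout.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical shape* of each stage's input at
the study's stated conditions, chosen once and fixed:

* score matrices: 30 conformers × 4 functions, per-function Gaussian scores
  on realistic fitness scales, one row shifted by a planted +3σ;
* energy tables: 100 snapshots (the last-nanosecond, every-10-ps cadence),
  i.i.d. Gaussian components around planted means, σ = 1 kcal/mol, with a
  four-site variant patterned on the published per-site totals;
* trajectories: 500 frames with a hydrogen bond planted in an exact
  ⌈p·frames⌉ subset (default p = 0.89); planting is deterministic, not
  Bernoulli, so recovery checks are sharp.

Gaussian noise is the simplest model consistent with mean ± std reporting;
real docking scores and MM/PBSA components are correlated across snapshots
and occasionally heavy-tailed, and real trajectories have conformational
autocorrelation that exact planting removes. Passing the synthetic
benchmarks therefore demonstrates the *correctness of the aggregation
arithmetic and detectors*, not the accuracy of docking or MM/PBSA on real
systems. Quantities that depend on external software — absolute docking
RMSDs, target-fishing list contents — are validated only as contracts on
synthetic data (e.g. the sub-2 Å classification and a 91-target fusion
round-trip).

Transcriptions of the published result tables ship as packaged CSVs with
frozen checksums, so acceptance checks never parse a manuscript at run
time.

## Pipeline

`run_pipeline` executes requested stages in the workflow order
fusion → consensus → energetics → interactions (plus a `fixtures` stage
that recomputes the reference-table numbers). Configuration is a
strictly-validated YAML (unknown keys rejected); every output CSV carries a
provenance header with the tool version, a config hash and input checksums.
Reruns with the same config are byte-identical — nothing in the pipeline is
time- or order-dependent.

## Problem sizes

Defaults throughout (30 conformers, 100 snapshots, 500 frames, 50-seed
recovery sweeps, 100–200 randomized oracle trials) were chosen as the sizes
a desk-scale reanalysis of this kind of study uses; the full test suite and
the acceptance script each run in well under a minute on one CPU.
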