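"""Geometric interaction analysis of MD snapshots and docking poses.

Works on lightweight structure frames (one set of atoms with coordinates) and
trajectories (ordered frames with a consistent atom roster), typically read
from multi-model PDB files.  Provides the standard post-MD analyses:

* hydrogen-bond detection (donor-acceptor heavy-atom distance, plus a
  D-H...A angle test whenever hydrogens are present in the model),
* residue-level heavy-atom contacts ("hydrophobic contact" networks),
* metal-coordination distances (e.g. a carbonyl oxygen to the catalytic
  Zn2+ of a metalloproteinase),
* occupancy: the fraction of trajectory frames in which a criterion holds,
* per-frame ligand RMSD against a reference pose (e.g. the initial docking
  structure), with optional receptor-backbone superposition,
* a ligand-residue interaction network weighted by contact frequency.

Atom selection uses a small glob grammar, ``chain:resname:resnum:atomname``,
where each field is an fnmatch pattern (``*`` matches anything), e.g.
``A:ARG:557:NH*`` or ``*:LIG:*:*``.

All detectors are pure functions of coordinates and criteria; distances are
evaluated with dense all-pairs arithmetic, which is exact and fast at the
system sizes these analyses see (a ligand against a binding site).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fnmatch import fnmatch
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .consensus import superpose_coords

__all__ = [
    "StructureFrame",
    "Trajectory",
    "Selector",
    "HBondCriterion",
    "ContactCriterion",
    "MetalCoordinationCriterion",
    "ResiduePairHBondCriterion",
    "OccupancyReport",
    "detect_hbond",
    "detect_contact",
    "metal_distance",
    "occupancy",
    "ligand_rmsd_series",
    "interaction_network",
    "load_criteria",
]

ATOM_COLUMNS = (
    "serial",
    "name",
    "element",
    "resname",
    "resnum",
    "chain",
    "x",
    "y",
    "z",
    "is_ligand",
)

# max heavy-atom -- hydrogen distance treated as a covalent bond
_H_BOND_LENGTH = 1.25

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class StructureFrame:
    """Atoms of one structure snapshot or docking pose.

    ``atoms`` columns: serial, name, element, resname, resnum, chain,
    x, y, z, is_ligand.  Coordinates are Angstrom.
    """

    atoms: pd.DataFrame
    frame_index: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"structure frame missing atom columns {missing}")
        if len(self.atoms) == 0:
            raise ValueError("structure frame has no atoms")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("structure frame contains non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def ligand(self) -> "StructureFrame":
        """Sub-frame of ligand atoms only."""
        sub = self.atoms[self.atoms["is_ligand"]]
        if len(sub) == 0:
            raise ValueError("frame contains no ligand atoms")
        return StructureFrame(atoms=sub.reset_index(drop=True), frame_index=self.frame_index)

    def roster(self) -> tuple:
        """Identity of the atom list, used to check trajectory consistency."""
        return tuple(zip(self.atoms["chain"], self.atoms["resnum"], self.atoms["name"]))


@dataclass(frozen=True)
class Trajectory:
    """Ordered structure frames with a consistent atom roster."""

    frames: tuple

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("trajectory has no frames")
        ref = self.frames[0].roster()
        for i, frame in enumerate(self.frames):
            if frame.roster() != ref:
                raise ValueError(
                    f"frame {i} atom roster differs from frame 0 "
                    f"({frame.n_atoms} vs {self.frames[0].n_atoms} atoms or reordered)"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> StructureFrame:
        return self.frames[i]

    @classmethod
    def from_frames(cls, frames: Iterable[StructureFrame]) -> "Trajectory":
        return cls(frames=tuple(frames))


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Selector:
    """Glob atom selector ``chain:resname:resnum:atomname``."""

    chain: str = "*"
    resname: str = "*"
    resnum: str = "*"
    atomname: str = "*"

    @classmethod
    def parse(cls, pattern: str) -> "Selector":
        parts = pattern.split(":")
        if len(parts) > 4:
            raise ValueError(
                f"selector {pattern!r} has more than 4 fields "
                "(grammar: chain:resname:resnum:atomname)"
            )
        parts += ["*"] * (4 - len(parts))
        return cls(*[p if p else "*" for p in parts])

    def mask(self, frame: StructureFrame) -> np.ndarray:
        atoms = frame.atoms
        m = np.ones(len(atoms), dtype=bool)
        if self.chain != "*":
            m &= np.array([fnmatch(str(c), self.chain) for c in atoms["chain"]])
        if self.resname != "*":
            m &= np.array([fnmatch(str(r), self.resname) for r in atoms["resname"]])
        if self.resnum != "*":
            m &= np.array([fnmatch(str(n), self.resnum) for n in atoms["resnum"]])
        if self.atomname != "*":
            m &= np.array([fnmatch(str(a), self.atomname) for a in atoms["name"]])
        return m

    def select(self, frame: StructureFrame, what: str = "selector") -> pd.DataFrame:
        mask = self.mask(frame)
        sub = frame.atoms[mask]
        if len(sub) == 0:
            raise ValueError(f"{what} {self.pattern()!r} matches zero atoms")
        return sub

    def pattern(self) -> str:
        return f"{self.chain}:{self.resname}:{self.resnum}:{self.atomname}"

    def restricted_to_chain(self, chain: str) -> "Selector":
        return Selector(chain=str(chain), resname=self.resname,
                        resnum=self.resnum, atomname=self.atomname)


def _as_selector(sel) -> Selector:
    return sel if isinstance(sel, Selector) else Selector.parse(str(sel))


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HBondCriterion:
    """Hydrogen bond between a donor selection and an acceptor selection.

    Satisfied when some donor-acceptor heavy-atom pair is within
    ``distance_cutoff`` and, if a hydrogen is covalently attached to the
    donor atom, the D-H...A angle is at least ``angle_cutoff`` degrees.
    When the model carries no hydrogens the distance test alone decides.
    """

    donor: str
    acceptor: str
    distance_cutoff: float = 3.5
    angle_cutoff: float = 120.0
    label: str = "hbond"

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0 < self.angle_cutoff <= 180):
            raise ValueError("angle cutoff must be in (0, 180] degrees")


@dataclass(frozen=True)
class ContactCriterion:
    """Heavy-atom contact between two selections (default 4.5 Angstrom)."""

    group_a: str
    group_b: str
    cutoff: float = 4.5
    label: str = "contact"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("distance cutoff must be positive")


@dataclass(frozen=True)
class MetalCoordinationCriterion:
    """Minimum ligand-atom to metal distance; coordinating iff < threshold."""

    ligand_atoms: str
    metal: str
    threshold: float = 2.6
    label: str = "metal_coordination"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("distance threshold must be positive")


# residue_pair_hbond is an HBondCriterion between two receptor residues;
# kept as an alias so YAML configs read naturally
ResiduePairHBondCriterion = HBondCriterion

_CRITERION_KINDS = {
    "hbond": HBondCriterion,
    "residue_pair_hbond": HBondCriterion,
    "contact": ContactCriterion,
    "metal_coordination": MetalCoordinationCriterion,
}


def criterion_from_dict(spec: Mapping) -> object:
    """Build a criterion from a mapping with a ``kind`` field (YAML entry)."""
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind not in _CRITERION_KINDS:
        raise ValueError(
            f"unknown criterion kind {kind!r}; expected one of {sorted(_CRITERION_KINDS)}"
        )
    if kind == "residue_pair_hbond":
        spec.setdefault("label", "residue_pair_hbond")
    return _CRITERION_KINDS[kind](**spec)


def load_criteria(path: str | Path) -> list:
    """Load a list of criteria from a YAML file."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, list):
        raise ValueError("criteria YAML must be a list of criterion mappings")
    return [criterion_from_dict(entry) for entry in doc]


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------


def _pairwise_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def _heavy(sub: pd.DataFrame) -> pd.DataFrame:
    return sub[sub["element"].str.upper() != "H"]


def _attached_hydrogens(frame: StructureFrame, donor_row: pd.Series) -> pd.DataFrame:
    """Hydrogens covalently bonded to the donor heavy atom (same residue)."""
    atoms = frame.atoms
    same_res = (
        (atoms["chain"] == donor_row["chain"])
        & (atoms["resnum"] == donor_row["resnum"])
        & (atoms["element"].str.upper() == "H")
    )
    hs = atoms[same_res]
    if len(hs) == 0:
        return hs
    d = np.linalg.norm(
        hs[["x", "y", "z"]].to_numpy(dtype=float)
        - donor_row[["x", "y", "z"]].to_numpy(dtype=float),
        axis=1,
    )
    return hs[d <= _H_BOND_LENGTH]


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbond(
    frame: StructureFrame, criterion: HBondCriterion
) -> tuple[bool, list[tuple[int, int]]]:
    """Evaluate a hydrogen-bond criterion on one frame.

    Returns ``(satisfied, pairs)`` where pairs are (donor serial, acceptor
    serial) for every donor-acceptor pair passing the geometric tests.
    """
    donors = _heavy(_as_selector(criterion.donor).select(frame, "donor selector"))
    acceptors = _heavy(_as_selector(criterion.acceptor).select(frame, "acceptor selector"))
    dcoords = donors[["x", "y", "z"]].to_numpy(dtype=float)
    acoords = acceptors[["x", "y", "z"]].to_numpy(dtype=float)
    dist = _pairwise_distances(dcoords, acoords)

    pairs: list[tuple[int, int]] = []
    for i, (_, drow) in enumerate(donors.iterrows()):
        hydrogens = _attached_hydrogens(frame, drow)
        for j, (_, arow) in enumerate(acceptors.iterrows()):
            if dist[i, j] > criterion.distance_cutoff:
                continue
            if dist[i, j] == 0.0:  # same atom selected as donor and acceptor
                continue
            if len(hydrogens) > 0:
                apos = arow[["x", "y", "z"]].to_numpy(dtype=float)
                dpos = drow[["x", "y", "z"]].to_numpy(dtype=float)
                ok = any(
                    _angle_deg(dpos, h[["x", "y", "z"]].to_numpy(dtype=float), apos)
                    >= criterion.angle_cutoff
                    for _, h in hydrogens.iterrows()
                )
                if not ok:
                    continue
            pairs.append((int(drow["serial"]), int(arow["serial"])))
    return (len(pairs) > 0, pairs)


def _residue_key(row: pd.Series) -> tuple:
    return (str(row["chain"]), str(row["resname"]), int(row["resnum"]))


def detect_contact(frame: StructureFrame, criterion: ContactCriterion) -> set:
    """Residue pairs of the two selections with any heavy-atom pair in range.

    Returns a set of frozensets ``{(chain, resname, resnum), ...}`` — one per
    contacting residue pair; contacts within the same residue are ignored.
    """
    a = _heavy(_as_selector(criterion.group_a).select(frame, "contact selector A"))
    b = _heavy(_as_selector(criterion.group_b).select(frame, "contact selector B"))
    dist = _pairwise_distances(
        a[["x", "y", "z"]].to_numpy(dtype=float),
        b[["x", "y", "z"]].to_numpy(dtype=float),
    )
    contacts = set()
    ii, jj = np.nonzero(dist <= criterion.cutoff)
    a_keys = [_residue_key(r) for _, r in a.iterrows()]
    b_keys = [_residue_key(r) for _, r in b.iterrows()]
    for i, j in zip(ii, jj):
        ka, kb = a_keys[i], b_keys[j]
        if ka != kb:
            contacts.add(frozenset((ka, kb)))
    return contacts


def metal_distance(
    frame: StructureFrame,
    ligand_atoms: str | Selector,
    metal: str | Selector,
    threshold: float = 2.6,
) -> tuple[float, bool]:
    """Minimum distance from selected ligand atoms to a single metal ion.

    Returns ``(distance, coordinating)`` with coordinating true iff the
    distance is strictly below ``threshold`` (default 2.6 Angstrom, the
    conventional upper bound for O-Zn2+ coordination).
    """
    lig = _heavy(_as_selector(ligand_atoms).select(frame, "ligand-atom selector"))
    met = _as_selector(metal).select(frame, "metal selector")
    if len(met) != 1:
        raise ValueError(
            f"metal selector must match exactly one atom, matched {len(met)}"
        )
    d = np.linalg.norm(
        lig[["x", "y", "z"]].to_numpy(dtype=float)
        - met[["x", "y", "z"]].to_numpy(dtype=float)[0],
        axis=1,
    )
    dmin = float(d.min())
    return dmin, dmin < threshold


def _satisfied(frame: StructureFrame, criterion) -> bool:
    if isinstance(criterion, HBondCriterion):
        return detect_hbond(frame, criterion)[0]
    if isinstance(criterion, ContactCriterion):
        return len(detect_contact(frame, criterion)) > 0
    if isinstance(criterion, MetalCoordinationCriterion):
        return metal_distance(
            frame, criterion.ligand_atoms, criterion.metal, criterion.threshold
        )[1]
    raise TypeError(f"unsupported criterion type {type(criterion).__name__}")


@dataclass(frozen=True)
class OccupancyReport:
    """Fraction of frames in which an interaction criterion is satisfied."""

    label: str
    satisfied_frames: int
    total_frames: int

    @property
    def frequency(self) -> float:
        return self.satisfied_frames / self.total_frames


def occupancy(
    traj: Trajectory,
    criterion,
    group_by_chain: bool = False,
) -> OccupancyReport | dict[str, OccupancyReport]:
    """Evaluate a criterion on every frame and report its occupancy.

    With ``group_by_chain=True`` the criterion is specialized to each chain
    present (both selectors restricted to that chain), returning one report
    per chain — the natural way to analyze one binding site per subunit of
    a homotetramer separately.
    """
    if not group_by_chain:
        count = sum(_satisfied(frame, criterion) for frame in traj)
        return OccupancyReport(
            label=getattr(criterion, "label", "criterion"),
            satisfied_frames=int(count),
            total_frames=len(traj),
        )
    chains = sorted(set(traj[0].atoms["chain"].astype(str)))
    out = {}
    for chain in chains:
        out[chain] = occupancy(traj, _restrict_criterion(criterion, chain))
    return out


def _restrict_criterion(criterion, chain: str):
    def restrict(pattern: str) -> str:
        return _as_selector(pattern).restricted_to_chain(chain).pattern()

    if isinstance(criterion, HBondCriterion):
        return HBondCriterion(
            donor=restrict(criterion.donor),
            acceptor=restrict(criterion.acceptor),
            distance_cutoff=criterion.distance_cutoff,
            angle_cutoff=criterion.angle_cutoff,
            label=f"{criterion.label}[{chain}]",
        )
    if isinstance(criterion, ContactCriterion):
        return ContactCriterion(
            group_a=restrict(criterion.group_a),
            group_b=restrict(criterion.group_b),
            cutoff=criterion.cutoff,
            label=f"{criterion.label}[{chain}]",
        )
    if isinstance(criterion, MetalCoordinationCriterion):
        return MetalCoordinationCriterion(
            ligand_atoms=restrict(criterion.ligand_atoms),
            metal=restrict(criterion.metal),
            threshold=criterion.threshold,
            label=f"{criterion.label}[{chain}]",
        )
    raise TypeError(f"unsupported criterion type {type(criterion).__name__}")


# ---------------------------------------------------------------------------
# ligand RMSD series
# ---------------------------------------------------------------------------


def ligand_rmsd_series(
    traj: Trajectory,
    reference: StructureFrame,
    superpose_backbone: bool = False,
) -> np.ndarray:
    """Per-frame heavy-atom RMSD of the ligand against a reference pose.

    The reference is typically the initial docking structure.  With
    ``superpose_backbone=True`` each frame's receptor backbone (N, CA, C, O)
    is first least-squares fitted onto the reference backbone and the
    transform applied to the whole frame, removing global receptor drift.
    """
    ref_lig = reference.ligand()
    ref_heavy = _heavy(ref_lig.atoms)
    ref_names = list(ref_heavy["name"])
    ref_coords = ref_heavy[["x", "y", "z"]].to_numpy(dtype=float)

    if superpose_backbone:
        ref_bb = reference.atoms[
            (~reference.atoms["is_ligand"])
            & reference.atoms["name"].isin(BACKBONE_NAMES)
        ]
        if len(ref_bb) < 3:
            raise ValueError("superposition requested but <3 receptor backbone atoms found")
        ref_bb_coords = ref_bb[["x", "y", "z"]].to_numpy(dtype=float)

    series = np.empty(len(traj))
    for k, frame in enumerate(traj):
        lig = _heavy(frame.ligand().atoms)
        names = list(lig["name"])
        if names != ref_names:
            raise ValueError(
                f"frame {k} ligand atom roster differs from the reference "
                f"({len(names)} vs {len(ref_names)} heavy atoms or reordered)"
            )
        coords = lig[["x", "y", "z"]].to_numpy(dtype=float)
        if superpose_backbone:
            bb = frame.atoms[
                (~frame.atoms["is_ligand"]) & frame.atoms["name"].isin(BACKBONE_NAMES)
            ]
            bb_coords = bb[["x", "y", "z"]].to_numpy(dtype=float)
            if bb_coords.shape != ref_bb_coords.shape:
                raise ValueError(f"frame {k} backbone roster differs from the reference")
            # fit the frame backbone onto the reference, apply to the ligand
            from scipy.spatial.transform import Rotation

            mc, tc = bb_coords.mean(axis=0), ref_bb_coords.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_bb_coords - tc, bb_coords - mc)
            coords = rot.apply(coords - mc) + tc
        delta = coords - ref_coords
        series[k] = np.sqrt(np.mean(np.sum(delta * delta, axis=1)))
    return series


def is_stable(series: np.ndarray, window: int | None = None, std_threshold: float = 1.0) -> bool:
    """Stability contract: std of the trailing window below a threshold.

    ``window`` defaults to the full series; for a 5 ns run sampled every
    2 ps the conventional check is the last-nanosecond window.
    """
    series = np.asarray(series, dtype=float)
    tail = series if window is None else series[-window:]
    return float(np.std(tail)) < std_threshold


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------


def interaction_network(
    traj: Trajectory,
    ligand_selector: str | Selector = "*:LIG:*:*",
    cutoff: float = 4.5,
    ligand_label: str = "LIGAND",
) -> tuple[nx.Graph, pd.DataFrame]:
    """Ligand-residue contact network weighted by occupancy frequency.

    Each receptor residue that contacts the ligand (any heavy-atom pair
    within ``cutoff``) in at least one frame becomes a node; the
    ligand-residue edge weight is the fraction of frames with a contact.

    Returns the graph and a tidy edge list (chain, resname, resnum, weight)
    sorted by descending weight.
    """
    sel = _as_selector(ligand_selector)
    counts: dict[tuple, int] = {}
    for frame in traj:
        lig = _heavy(sel.select(frame, "ligand selector"))
        env = _heavy(frame.atoms[~sel.mask(frame)])
        if len(env) == 0:
            continue
        dist = _pairwise_distances(
            lig[["x", "y", "z"]].to_numpy(dtype=float),
            env[["x", "y", "z"]].to_numpy(dtype=float),
        )
        hit = dist.min(axis=0) <= cutoff
        seen = {(str(r["chain"]), str(r["resname"]), int(r["resnum"]))
                for _, r in env[hit].iterrows()}
        for key in seen:
            counts[key] = counts.get(key, 0) + 1

    n = len(traj)
    graph = nx.Graph()
    graph.add_node(ligand_label, kind="ligand")
    rows = []
    for (chain, resname, resnum), c in counts.items():
        node = f"{chain}:{resname}:{resnum}"
        weight = c / n
        graph.add_node(node, chain=chain, resname=resname, resnum=resnum, kind="residue")
        graph.add_edge(ligand_label, node, weight=weight)
        rows.append({"chain": chain, "resname": resname, "resnum": resnum, "weight": weight})
    edges = pd.DataFrame(rows, columns=["chain", "resname", "resnum", "weight"])
    edges = edges.sort_values(
        ["weight", "chain", "resnum"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return graph, edges
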