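"""Shared fixtures: small hand-built tables and random structure frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from targetid.interactions import ATOM_COLUMNS, StructureFrame


def make_frame(rows, frame_index: int = 0) -> StructureFrame:
    """Build a StructureFrame from raw atom tuples."""
    return StructureFrame(
        atoms=pd.DataFrame(rows, columns=list(ATOM_COLUMNS)), frame_index=frame_index
    )


def random_frame(rng: np.random.Generator, n_atoms: int = 50, box: float = 12.0) -> StructureFrame:
    """Random mixed-element frame: one ligand residue plus receptor residues.

    Atoms are scattered uniformly in a box; roughly one in five is a
    hydrogen, parked next to the preceding heavy atom so some of them count
    as covalently bonded donor hydrogens.
    """
    rows = []
    elements = ["C", "N", "O"]
    coords = rng.uniform(0, box, size=(n_atoms, 3))
    for i in range(n_atoms):
        is_ligand = i < n_atoms // 4
        resnum = 900 if is_ligand else 10 + (i % 6)
        resname = "LIG" if is_ligand else ["ALA", "SER", "ARG", "GLU", "LEU", "THR"][i % 6]
        if rng.random() < 0.2 and i > 0:
            element, name = "H", f"H{i}"
            coords[i] = coords[i - 1] + rng.normal(0, 0.3, size=3) * 0.5
            if np.linalg.norm(coords[i] - coords[i - 1]) > 1.2:
                coords[i] = coords[i - 1] + (coords[i] - coords[i - 1]) * 0.5
        else:
            element = elements[int(rng.integers(3))]
            name = f"{element}{i}"
        rows.append(
            (i + 1, name, element, resname, resnum, "A",
             float(coords[i][0]), float(coords[i][1]), float(coords[i][2]), is_ligand)
        )
    return make_frame(rows)


@pytest.fixture
def toy_predictions():
    """Three methods, overlapping target lists, M = 3."""
    return [
        ("T1", "m1", 1), ("T2", "m1", 2), ("T3", "m1", 3), ("T4", "m1", 4),
        ("T1", "m2", 1), ("T3", "m2", 2),
        ("T1", "m3", 1), ("T5", "m3", 2), ("T2", "m3", 3),
    ]
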