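"""Reading and writing structure frames as (multi-model) PDB.

PDB is the only structural format handled in core: docking poses are single
models (or one MODEL per conformer) and MD snapshot ensembles are multi-model
files delimited by MODEL/ENDMDL.  Parsing is delegated to Bio.PDB; this
module converts to the flat atom tables used by the analysis code and back.

Ligand atoms are flagged by residue name (default ``LIG``), which matches the
HETATM naming convention used for docked small molecules.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .interactions import ATOM_COLUMNS, StructureFrame, Trajectory

__all__ = ["read_pdb", "read_trajectory", "write_pdb", "DEFAULT_LIGAND_RESNAMES"]

DEFAULT_LIGAND_RESNAMES = ("LIG", "UNL", "UNK")


def _validate_records(path: Path) -> None:
    """Cheap fixed-width sanity check so errors carry line numbers."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ValueError(f"{path.name}:{lineno}: truncated coordinate record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed coordinate fields "
                    f"{line[30:54]!r}"
                ) from None


def _frame_from_model(model, ligand_resnames: Sequence[str], index: int) -> StructureFrame:
    rows = []
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            resnum = residue.id[1]
            for atom in residue:
                element = (atom.element or "").strip() or atom.get_name().strip()[0]
                x, y, z = atom.coord
                rows.append(
                    (
                        atom.serial_number,
                        atom.get_name().strip(),
                        element.upper(),
                        resname,
                        int(resnum),
                        str(chain.id).strip() or "A",
                        float(x),
                        float(y),
                        float(z),
                        resname in ligand_resnames,
                    )
                )
    atoms = pd.DataFrame(rows, columns=list(ATOM_COLUMNS))
    return StructureFrame(atoms=atoms, frame_index=index)


def read_pdb(
    path: str | Path,
    ligand_resnames: Sequence[str] = DEFAULT_LIGAND_RESNAMES,
) -> StructureFrame | Trajectory:
    """Read a PDB file; multi-model files yield a :class:`Trajectory`.

    Element symbols come from columns 77-78 when present, falling back to
    the first character of the atom name.  Residue numbering is preserved
    as in the file (1-based).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_records(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    frames = [
        _frame_from_model(model, tuple(ligand_resnames), i)
        for i, model in enumerate(structure)
    ]
    if len(frames) == 0:
        raise ValueError(f"{path.name}: no coordinate records found")
    if len(frames) == 1:
        return frames[0]
    return Trajectory.from_frames(frames)


def read_trajectory(
    path: str | Path,
    ligand_resnames: Sequence[str] = DEFAULT_LIGAND_RESNAMES,
) -> Trajectory:
    """Read a PDB as a trajectory even if it holds a single model."""
    result = read_pdb(path, ligand_resnames)
    if isinstance(result, StructureFrame):
        return Trajectory.from_frames([result])
    return result


def _atom_line(row, serial: int) -> str:
    record = "HETATM" if row.is_ligand else "ATOM  "
    name = row.name_ if len(row.name_) >= 4 else f" {row.name_:<3s}"
    return (
        f"{record}{serial:>5d} {name:<4.4s} {row.resname:<3.3s} {row.chain:1.1s}"
        f"{int(row.resnum):>4d}    {row.x:8.3f}{row.y:8.3f}{row.z:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {row.element:>2.2s}"
    )


def write_pdb(frames: StructureFrame | Trajectory | Iterable[StructureFrame], path: str | Path) -> Path:
    """Write one or more frames as a (multi-model) PDB file.

    Coordinates are written at the format's native 3-decimal precision.
    """
    if isinstance(frames, StructureFrame):
        frames = [frames]
    frames = list(frames)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []
    multi = len(frames) > 1
    for k, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {k:>4d}")
        atoms = frame.atoms.rename(columns={"name": "name_"})
        for serial, row in enumerate(atoms.itertuples(index=False), start=1):
            lines.append(_atom_line(row, serial))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
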