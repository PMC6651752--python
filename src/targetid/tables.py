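"""Tabular I/O shared across the pipeline stages.

All tables are plain CSV/TSV with a header row.  The delimiter is
auto-detected, ``#`` lines are treated as comments (provenance headers written
by this package use them), and decimal points are always ``.`` regardless of
locale.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["read_table", "write_table", "file_sha256"]


def read_table(
    path: str | Path,
    required: Sequence[str] = (),
    numeric: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a delimited text table with schema validation.

    Parameters
    ----------
    path:
        CSV or TSV file; the delimiter is sniffed.
    required:
        Column names that must be present.
    numeric:
        Columns coerced to float; a non-numeric cell raises naming the
        offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    if len(frame) == 0:
        raise ValueError(f"{path.name}: empty data section")
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path.name}: non-numeric value {frame.loc[row, col]!r} "
                f"in column {col!r}, row {row}"
            )
        frame[col] = coerced
    return frame


def file_sha256(path: str | Path) -> str:
    """Hex SHA-256 of a file's bytes."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, str] | None = None,
    float_format: str | None = None,
) -> Path:
    """Write a CSV with an optional ``#``-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if provenance:
        for key, value in provenance.items():
            lines.append(f"# {key}: {value}")
    body = frame.to_csv(index=False, float_format=float_format)
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)
    return path


def provenance_header(
    tool_version: str,
    config_hash: str = "",
    inputs: Iterable[str | Path] = (),
) -> dict:
    """Standard provenance fields stamped on every output table."""
    head = {"generated-by": f"targetid {tool_version}"}
    if config_hash:
        head["config-sha256"] = config_hash
    for p in inputs:
        p = Path(p)
        if p.exists():
            head[f"input-sha256 {p.name}"] = file_sha256(p)
    return head
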