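"""Minimal reader/writer for the STAR metadata format used in electron microscopy.

A STAR file holds named data blocks (``data_<name>``); each block is either a
``loop_`` table or a list of ``_label value`` pairs.  Both forms are parsed
into a :class:`pandas.DataFrame` (key-value blocks become a single-row frame).
All values are kept as *strings* on read, so that unknown vendor columns
survive a read/write cycle byte-identically; typed access is the caller's
responsibility (see :mod:`tomopipe.metadata`).

Writing always emits ``loop_`` tables.  Floats are formatted with 6
significant digits, which keeps diffs stable and round-trips real values to
better than 1e-6 relative.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

__all__ = ["read_star", "write_star", "format_value"]


class StarParseError(ValueError):
    """Raised when a STAR file cannot be parsed; the message names the line."""


def format_value(v: object) -> str:
    """Format one cell for STAR output.

    Floats get 7 significant digits: enough that a write/read cycle stays
    within 1e-6 relative while keeping diffs stable.
    """
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        if math.isnan(v):
            return "nan"
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return f"{v:.7g}"
    return str(v)


def read_star(path: str | Path) -> dict[str, pd.DataFrame]:
    """Parse *path* into an ordered mapping of block name -> DataFrame.

    Every cell is returned as ``str``; comments (``#``) and blank lines are
    skipped.  Quoted tokens are not supported (no STAR file in this pipeline
    contains whitespace in values).
    """
    path = Path(path)
    blocks: dict[str, pd.DataFrame] = {}
    lines = path.read_text().splitlines()

    name = None
    labels: list[str] = []
    rows: list[list[str]] = []
    kv: dict[str, str] = {}
    in_loop = False

    def flush() -> None:
        nonlocal labels, rows, kv, in_loop
        if name is not None:
            if labels:
                blocks[name] = pd.DataFrame(rows, columns=labels, dtype=str)
            elif kv:
                blocks[name] = pd.DataFrame([list(kv.values())], columns=list(kv), dtype=str)
            else:
                blocks[name] = pd.DataFrame()
        labels, rows, kv, in_loop = [], [], {}, False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip() if raw.lstrip().startswith("#") else raw.strip()
        if not line:
            continue
        if line.startswith("data_"):
            flush()
            name = line[5:]
            continue
        if line == "loop_":
            in_loop = True
            continue
        if line.startswith("_"):
            parts = line.split(None, 1)
            label = parts[0].lstrip("_")
            if in_loop:
                labels.append(label)
            else:
                if len(parts) != 2:
                    raise StarParseError(f"{path}:{lineno}: label without value: {raw!r}")
                kv[label] = parts[1].strip()
            continue
        if name is None:
            raise StarParseError(f"{path}:{lineno}: data outside a data_ block: {raw!r}")
        values = line.split()
        if labels and len(values) != len(labels):
            raise StarParseError(
                f"{path}:{lineno}: expected {len(labels)} values, got {len(values)}"
            )
        rows.append(values)
    flush()
    return blocks


def write_star(path: str | Path, blocks: dict[str, pd.DataFrame]) -> Path:
    """Write *blocks* to *path* as loop_ tables, one per data block."""
    path = Path(path)
    out: list[str] = []
    for name, df in blocks.items():
        out.append(f"data_{name}")
        out.append("")
        out.append("loop_")
        for i, col in enumerate(df.columns, start=1):
            out.append(f"_{col} #{i}")
        for _, row in df.iterrows():
            out.append("\t".join(format_value(v) for v in row))
        out.append("")
    path.write_text("\n".join(out) + "\n")
    return path
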