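"""Minimal NMR-STAR v3 assigned-chemical-shift loop reader/writer.

Covers the single dialect this package emits: one ``_Atom_chem_shift`` loop
with ``Seq_ID``, ``Comp_ID``, ``Atom_ID`` and ``Val`` tags (extra tags are
ignored on read).  This is deliberately not a general STAR parser; deposited
files restricted to the assigned-chemical-shift loop, such as the subset a
BMRB entry exports, parse fine, but framecode indirection and multi-line
values do not.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, TextIO

from oxaribo.errors import FormatError

_REQUIRED = ("Seq_ID", "Comp_ID", "Atom_ID", "Val")


def read_shift_loop(handle: TextIO) -> list[tuple[int, str, str, float]]:
    """Parse the first ``_Atom_chem_shift`` loop into (seq, comp3, atom, value) rows."""
    tags: list[str] = []
    rows: list[tuple[int, str, str, float]] = []
    in_loop = False
    in_data = False
    for lineno, raw in enumerate(handle, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line == "loop_":
            in_loop, in_data, tags = True, False, []
            continue
        if line == "stop_":
            if in_data and rows:
                break
            in_loop = in_data = False
            continue
        if in_loop and line.startswith("_"):
            if in_data:
                raise FormatError(f"line {lineno}: tag after data rows began")
            tags.append(line.split(".")[-1])
            continue
        if in_loop and tags:
            if not any(t in _REQUIRED for t in tags):
                in_loop = False  # some other loop; skip its rows
                continue
            in_data = True
            tokens = line.split()
            if len(tokens) != len(tags):
                raise FormatError(
                    f"line {lineno}: expected {len(tags)} fields, got {len(tokens)}"
                )
            record = dict(zip(tags, tokens))
            missing = [t for t in _REQUIRED if t not in record]
            if missing:
                raise FormatError(f"line {lineno}: loop lacks required tags {missing}")
            try:
                rows.append(
                    (
                        int(record["Seq_ID"]),
                        record["Comp_ID"].upper(),
                        record["Atom_ID"].upper(),
                        float(record["Val"]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    if not rows:
        raise FormatError("no _Atom_chem_shift loop with data rows found")
    return rows


def write_shift_loop(
    handle: TextIO, rows: Iterable[tuple[int, str, str, float]], entry: str = "oxaribo"
) -> None:
    handle.write(f"data_{entry}\n\nsave_assigned_chemical_shifts\n")
    handle.write("   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts\n")
    handle.write("   loop_\n")
    for tag in ("ID",) + _REQUIRED:
        handle.write(f"      _Atom_chem_shift.{tag}\n")
    for i, (seq, comp, atom, val) in enumerate(rows, start=1):
        handle.write(f"      {i} {seq} {comp} {atom} {val:.3f}\n")
    handle.write("   stop_\nsave_\n")


def read_shift_loop_path(path: str | Path) -> list[tuple[int, str, str, float]]:
    with open(path) as handle:
        return read_shift_loop(handle)
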