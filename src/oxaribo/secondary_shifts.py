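"""Secondary chemical shifts and helix/coil segment classification.

The secondary chemical shift of a residue is its observed shift minus a
random-coil reference.  The difference form used here,

    delta = (dCA_obs - dCA_rc) - (dCB_obs - dCB_rc),

is positive in alpha-helices and negative in beta-strands; consecutive values
near +3 ppm indicate a well-formed helix, intermediate positive values (about
+1 to +2 ppm) a transient, partially populated helix, and values near zero a
random coil.  Segment classification smooths the per-residue profile with a
centered running mean and cuts it at configurable thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from oxaribo import _nmrstar
from oxaribo.errors import ConfigurationError, FormatError, ValidationError
from oxaribo.random_coil import AA1, AA1_FROM_3, AA3, RandomCoilTable, wishart_1995

NUCLEI = ("H", "N", "CA", "CB", "C")

# Soft plausibility windows in ppm; violations warn, never fail.
_PLAUSIBLE = {"CA": (40.0, 70.0), "CB": (15.0, 75.0), "N": (100.0, 135.0), "H": (6.0, 11.0)}


@dataclass
class ShiftEntry:
    residue_number: int
    residue_type: str
    shifts: dict[str, float] = field(default_factory=dict)


@dataclass
class ShiftTable:
    """Ordered per-residue assigned backbone chemical shifts.

    Invariants: residue numbers unique and strictly increasing; residue types
    one-letter standard codes; glycines never carry a CB shift.
    """

    entries: list[ShiftEntry]

    def __post_init__(self) -> None:
        numbers = [e.residue_number for e in self.entries]
        if len(set(numbers)) != len(numbers):
            raise ValidationError("duplicate residue numbers in shift table")
        if numbers != sorted(numbers):
            self.entries = sorted(self.entries, key=lambda e: e.residue_number)
        for e in self.entries:
            if e.residue_type not in AA1:
                raise ValidationError(
                    f"residue {e.residue_number}: unknown residue code {e.residue_type!r}"
                )
            if e.residue_type == "G" and "CB" in e.shifts:
                raise ValidationError(f"glycine {e.residue_number} carries a CB shift")
            for nuc in e.shifts:
                if nuc not in NUCLEI:
                    raise ValidationError(
                        f"residue {e.residue_number}: unknown nucleus {nuc!r}"
                    )
        for e in self.entries:
            for nuc, (lo, hi) in _PLAUSIBLE.items():
                val = e.shifts.get(nuc)
                if val is not None and not lo <= val <= hi:
                    import warnings

                    warnings.warn(
                        f"residue {e.residue_number} {nuc}={val:.2f} ppm outside "
                        f"plausible window [{lo}, {hi}]",
                        stacklevel=2,
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def residue_numbers(self) -> list[int]:
        return [e.residue_number for e in self.entries]

    def types_by_number(self) -> dict[int, str]:
        return {e.residue_number: e.residue_type for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns residue_number, residue_type, nucleus, shift_ppm."""
        rows = [
            (e.residue_number, e.residue_type, nuc, val)
            for e in self.entries
            for nuc, val in sorted(e.shifts.items())
        ]
        return pd.DataFrame(
            rows, columns=["residue_number", "residue_type", "nucleus", "shift_ppm"]
        )


ProfileStatus = Literal["ok", "ca_only", "missing"]


@dataclass
class SecondaryShiftProfile:
    """Per-residue delta = ddCA - ddCB values with availability status."""

    residue_numbers: list[int]
    deltas: list[float | None]
    statuses: list[ProfileStatus]

    def __post_init__(self) -> None:
        for d, s in zip(self.deltas, self.statuses):
            if (d is None) != (s == "missing"):
                raise ValidationError("delta must be present exactly when status != missing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_number": self.residue_numbers,
                "delta_ppm": [math.nan if d is None else d for d in self.deltas],
                "status": self.statuses,
            }
        )


SegmentClass = Literal["stable_helix", "transient_helix", "coil", "extended"]


@dataclass
class StructuralSegment:
    start_residue: int
    end_residue: int
    segment_class: SegmentClass
    mean_delta: float
    n_residues_with_data: int

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ValidationError("segment start must not exceed end")

    def covers(self, residue: int) -> bool:
        return self.start_residue <= residue <= self.end_residue


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["residue_number", "residue_type", "nucleus", "shift_ppm"]


def read_shift_table(source: str | Path, dialect: str = "tsv") -> ShiftTable:
    """Read an assigned-shift table from a TSV or NMR-STAR v3 file.

    The TSV dialect expects a header row ``residue_number residue_type nucleus
    shift_ppm`` (tab-separated); residue_type may be a one- or three-letter
    code.  The nmrstar dialect reads the first assigned-chemical-shift loop.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        rows = _read_tsv_rows(path)
    elif dialect == "nmrstar":
        rows = [
            (seq, _comp_to_one(comp, path), atom, val)
            for seq, comp, atom, val in _nmrstar.read_shift_loop_path(path)
            if atom in NUCLEI
        ]
    else:
        raise ConfigurationError(f"unknown shift-table dialect {dialect!r}")
    return _rows_to_table(rows)


def _comp_to_one(comp: str, path: Path) -> str:
    if len(comp) == 1 and comp in AA1:
        return comp
    try:
        return AA1_FROM_3[comp]
    except KeyError:
        raise ValidationError(f"{path}: unknown residue code {comp!r}") from None


def _read_tsv_rows(path: Path) -> list[tuple[int, str, str, float]]:
    rows = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise FormatError(f"{path} line 1: expected header {_TSV_COLUMNS}, got {header}")
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path} line {lineno}: expected 4 fields, got {len(fields)}")
            try:
                num = int(fields[0])
                val = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            rtype = fields[1].strip().upper()
            if len(rtype) == 3:
                rtype = AA1_FROM_3.get(rtype, rtype)
            rows.append((num, rtype, fields[2].strip().upper(), val))
    return rows


def _rows_to_table(rows: Iterable[tuple[int, str, str, float]]) -> ShiftTable:
    entries: dict[int, ShiftEntry] = {}
    seen: set[tuple[int, str]] = set()
    for num, rtype, nucleus, val in rows:
        if (num, nucleus) in seen:
            raise ValidationError(f"duplicate assignment for residue {num} nucleus {nucleus}")
        seen.add((num, nucleus))
        entry = entries.setdefault(num, ShiftEntry(num, rtype))
        if entry.residue_type != rtype:
            raise ValidationError(f"residue {num} listed with conflicting types")
        entry.shifts[nucleus] = val
    return ShiftTable(list(entries.values()))


def write_shift_table(table: ShiftTable, dest: str | Path, dialect: str = "tsv") -> None:
    path = Path(dest)
    if dialect == "tsv":
        with open(path, "w") as handle:
            handle.write("\t".join(_TSV_COLUMNS) + "\n")
            for e in table.entries:
                for nuc in NUCLEI:
                    if nuc in e.shifts:
                        handle.write(
                            f"{e.residue_number}\t{e.residue_type}\t{nuc}\t"
                            f"{e.shifts[nuc]:.4f}\n"
                        )
    elif dialect == "nmrstar":
        rows = [
            (e.residue_number, AA3[e.residue_type], nuc, e.shifts[nuc])
            for e in table.entries
            for nuc in NUCLEI
            if nuc in e.shifts
        ]
        with open(path, "w") as handle:
            _nmrstar.write_shift_loop(handle, rows)
    else:
        raise ConfigurationError(f"unknown shift-table dialect {dialect!r}")


def write_profile(profile: SecondaryShiftProfile, segments: Sequence[StructuralSegment],
                  dest: str | Path) -> None:
    """Profile TSV with columns residue_number, delta_ppm, status, class."""
    by_residue: dict[int, str] = {}
    for seg in segments:
        for r in range(seg.start_residue, seg.end_residue + 1):
            by_residue[r] = seg.segment_class
    frame = profile.to_frame()
    frame["class"] = [by_residue.get(r, "") for r in frame["residue_number"]]
    frame.to_csv(dest, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Computation
# ---------------------------------------------------------------------------

def compute_secondary_shifts(
    table: ShiftTable,
    refs: RandomCoilTable | None = None,
    use_neighbor_corrections: bool = False,
    global_offset: float = 0.0,
) -> SecondaryShiftProfile:
    """Compute delta = (dCA_obs - dCA_rc) - (dCB_obs - dCB_rc) per residue.

    Glycines and residues lacking an observed CB report the CA-only secondary
    shift with status ``ca_only``; residues with no carbon data are
    ``missing``.  ``global_offset`` is subtracted from every observed carbon
    shift before referencing (re-referencing hook, default 0).
    ``use_neighbor_corrections`` applies the reference table's additive
    neighbor terms (built-in table: pre-proline CA correction only).
    """
    if refs is None:
        refs = wishart_1995()
    if len(table) == 0:
        raise ValidationError("empty shift table")
    types = table.types_by_number()
    numbers: list[int] = []
    deltas: list[float | None] = []
    statuses: list[ProfileStatus] = []
    for entry in table.entries:
        if entry.residue_type not in refs.ca:
            raise ConfigurationError(
                f"residue type {entry.residue_type!r} absent from random-coil table"
            )
        neighbors = None
        if use_neighbor_corrections:
            neighbors = {
                off: types[entry.residue_number + off]
                for off in (-1, +1)
                if entry.residue_number + off in types
            }
        ca_obs = entry.shifts.get("CA")
        cb_obs = entry.shifts.get("CB")
        numbers.append(entry.residue_number)
        if ca_obs is None:
            deltas.append(None)
            statuses.append("missing")
            continue
        d_ca = (ca_obs - global_offset) - refs.reference(entry.residue_type, "CA", neighbors)
        if cb_obs is None or entry.residue_type == "G":
            deltas.append(d_ca)
            statuses.append("ca_only")
        else:
            d_cb = (cb_obs - global_offset) - refs.reference(entry.residue_type, "CB", neighbors)
            deltas.append(d_ca - d_cb)
            statuses.append("ok")
    return SecondaryShiftProfile(numbers, deltas, statuses)


class SegmentClassifier(BaseEstimator):
    """Rule-based classifier cutting a smoothed secondary-shift profile into
    stable-helix / transient-helix / coil / extended segments.

    Parameters
    ----------
    stable, transient, coil : float, ppm
        Ordered thresholds (stable > transient > coil > 0).  A residue whose
        smoothed delta is >= ``stable`` is stable helix; in
        [``transient``, ``stable``) transient helix; <= ``-coil`` extended;
        otherwise coil.
    window : odd int
        Width of the centered running mean, counted over residues with data
        (edges shrink to the available neighbors).
    min_length : int
        Minimum segment span in residues; shorter non-coil runs are absorbed
        into coil.
    include_ca_only : bool
        Whether CA-only deltas (glycines, missing CB) enter the running mean.
    max_missing_gap : int
        Missing residues do not break a run when the numbering gap between
        consecutive data residues is at most this many residues.
    exclude_below : int or None
        Drop residues numbered below this (e.g. expression-tag remnants)
        before classification.

    The classifier is stateless; ``fit`` validates parameters and returns
    ``self``, and :meth:`predict` maps a profile to its segment list.
    """

    def __init__(
        self,
        stable: float = 2.0,
        transient: float = 0.5,
        coil: float = 0.5,
        window: int = 5,
        min_length: int = 4,
        include_ca_only: bool = False,
        max_missing_gap: int = 1,
        exclude_below: int | None = None,
    ):
        self.stable = stable
        self.transient = transient
        self.coil = coil
        self.window = window
        self.min_length = min_length
        self.include_ca_only = include_ca_only
        self.max_missing_gap = max_missing_gap
        self.exclude_below = exclude_below

    def _validate(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigurationError("window must be an odd integer >= 1")
        if not self.stable > self.transient > 0 or not self.coil > 0:
            raise ConfigurationError("thresholds must satisfy stable > transient > 0, coil > 0")
        if self.min_length < 1:
            raise ConfigurationError("min_length must be >= 1")

    def fit(self, X: SecondaryShiftProfile | None = None, y=None) -> "SegmentClassifier":
        self._validate()
        self.n_features_in_ = 1
        return self

    def predict(self, profile: SecondaryShiftProfile) -> list[StructuralSegment]:
        self._validate()
        statuses_ok = {"ok"} | ({"ca_only"} if self.include_ca_only else set())
        data = [
            (r, d)
            for r, d, s in zip(profile.residue_numbers, profile.deltas, profile.statuses)
            if s in statuses_ok
            and (self.exclude_below is None or r >= self.exclude_below)
        ]
        if not data:
            raise ValidationError("profile has no residues with usable secondary shifts")
        numbers = np.array([r for r, _ in data])
        deltas = np.array([d for _, d in data], dtype=float)

        half = self.window // 2
        smoothed = np.array(
            [
                deltas[max(0, j - half): j + half + 1].mean()
                for j in range(len(deltas))
            ]
        )
        classes = np.where(
            smoothed >= self.stable,
            "stable_helix",
            np.where(
                smoothed >= self.transient,
                "transient_helix",
                np.where(smoothed <= -self.coil, "extended", "coil"),
            ),
        )

        # maximal runs of equal class; numbering gaps > max_missing_gap break runs
        runs: list[dict] = []
        for j in range(len(numbers)):
            gap_break = j > 0 and numbers[j] - numbers[j - 1] - 1 > self.max_missing_gap
            if runs and not gap_break and runs[-1]["class"] == classes[j]:
                runs[-1]["end"] = int(numbers[j])
                runs[-1]["values"].append(smoothed[j])
            else:
                runs.append(
                    {
                        "class": str(classes[j]),
                        "start": int(numbers[j]),
                        "end": int(numbers[j]),
                        "values": [smoothed[j]],
                    }
                )

        # absorb short non-coil runs into coil, then merge adjacent coil runs
        for run in runs:
            if run["class"] != "coil" and run["end"] - run["start"] + 1 < self.min_length:
                run["class"] = "coil"
        merged: list[dict] = []
        for run in runs:
            if (
                merged
                and merged[-1]["class"] == run["class"] == "coil"
                and run["start"] - merged[-1]["end"] - 1 <= self.max_missing_gap
            ):
                merged[-1]["end"] = run["end"]
                merged[-1]["values"].extend(run["values"])
            else:
                merged.append(run)

        return [
            StructuralSegment(
                start_residue=run["start"],
                end_residue=run["end"],
                segment_class=run["class"],  # type: ignore[arg-type]
                mean_delta=float(np.mean(run["values"])),
                n_residues_with_data=len(run["values"]),
            )
            for run in merged
        ]

    # keep the transformer spelling available for pipeline composition
    def transform(self, profile: SecondaryShiftProfile) -> list[StructuralSegment]:
        return self.predict(profile)


def classify_segments(
    profile: SecondaryShiftProfile,
    thresholds: dict[str, float] | None = None,
    window: int = 5,
    min_length: int = 4,
    **kwargs,
) -> list[StructuralSegment]:
    """Functional wrapper over :class:`SegmentClassifier`."""
    thresholds = thresholds or {}
    clf = SegmentClassifier(
        stable=thresholds.get("stable", 2.0),
        transient=thresholds.get("transient", 0.5),
        coil=thresholds.get("coil", 0.5),
        window=window,
        min_length=min_length,
        **kwargs,
    )
    return clf.fit().predict(profile)
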