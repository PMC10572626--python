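"""Per-residue intensity ratios, chemical shift perturbations and
binding-segment calling from an HSQC/HMQC titration series.

A large, slowly tumbling binding partner (here the 70S ribosome) broadens the
resonances of residues in contact with it far beyond their bound population;
the observable is a per-residue intensity ratio I_bound / I_free that drops
most steeply at the binding site.  Chemical shift perturbations (CSPs) give an
independent, position-based readout under fast exchange.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from oxaribo.errors import FormatError, ValidationError
from oxaribo.random_coil import AA1


@dataclass
class Peak:
    residue_number: int
    residue_type: str
    position_h: float
    position_n: float
    intensity: float


@dataclass
class PeakList:
    """At most one assigned amide peak per residue, intensities > 0."""

    peaks: list[Peak]

    def __post_init__(self) -> None:
        numbers = [p.residue_number for p in self.peaks]
        if len(set(numbers)) != len(numbers):
            raise ValidationError("duplicate residue in peak list")
        for p in self.peaks:
            if p.intensity <= 0:
                raise ValidationError(
                    f"residue {p.residue_number}: intensity must be strictly positive"
                )
            if p.residue_type not in AA1:
                raise ValidationError(
                    f"residue {p.residue_number}: unknown residue code {p.residue_type!r}"
                )
        self.peaks = sorted(self.peaks, key=lambda p: p.residue_number)

    def __len__(self) -> int:
        return len(self.peaks)

    def by_residue(self) -> dict[int, Peak]:
        return {p.residue_number: p for p in self.peaks}

    def residue_numbers(self) -> set[int]:
        return {p.residue_number for p in self.peaks}


@dataclass
class TitrationPoint:
    molar_ratio: float  # protein-side number of the protein:partner ratio
    peaks: PeakList


@dataclass
class TitrationSeries:
    """Reference (partner-free) peak list plus points at decreasing
    protein:partner molar ratios (400 -> 5 means increasing partner)."""

    reference: PeakList
    points: list[TitrationPoint]
    protein_total: float  # uM

    def __post_init__(self) -> None:
        ratios = [p.molar_ratio for p in self.points]
        if len(set(ratios)) != len(ratios):
            raise ValidationError("molar ratios must be unique")
        if ratios != sorted(ratios, reverse=True):
            raise ValidationError("molar ratios must be strictly decreasing")
        ref_residues = self.reference.residue_numbers()
        for point in self.points:
            extra = point.peaks.residue_numbers() - ref_residues
            if extra:
                raise ValidationError(
                    f"point {point.molar_ratio}: residues {sorted(extra)} absent "
                    "from the reference list"
                )


@dataclass
class IntensityRatioProfile:
    """ratio(residue, molar_ratio) = I_point / I_reference, defined only where
    both peaks exist (a vanished peak is not-detected, not zero)."""

    ratios: dict[tuple[int, float], float]

    def at_point(self, molar_ratio: float) -> dict[int, float]:
        return {
            res: val
            for (res, ratio), val in self.ratios.items()
            if ratio == molar_ratio
        }

    def molar_ratios(self) -> list[float]:
        return sorted({mr for _, mr in self.ratios}, reverse=True)

    def to_frame(self) -> pd.DataFrame:
        rows = [(res, mr, val) for (res, mr), val in sorted(self.ratios.items())]
        return pd.DataFrame(rows, columns=["residue_number", "molar_ratio", "ratio"])


@dataclass
class CSPProfile:
    """Combined 1H/15N chemical shift perturbations per residue."""

    residue_numbers: list[int]
    d_h: list[float]
    d_n: list[float]
    csp: list[float]
    significant: list[bool]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_number": self.residue_numbers,
                "dH": self.d_h,
                "dN": self.d_n,
                "csp": self.csp,
                "significant": self.significant,
            }
        )


@dataclass
class BindingSegment:
    start_residue: int
    end_residue: int
    mean_ratio: float


@dataclass
class BindingSiteCall:
    segments: list[BindingSegment]
    calling_ratio_point: float
    baseline_ratio: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "calling_ratio_point": self.calling_ratio_point,
                "baseline_ratio": self.baseline_ratio,
                "segments": [
                    {
                        "start_residue": s.start_residue,
                        "end_residue": s.end_residue,
                        "mean_ratio": s.mean_ratio,
                    }
                    for s in self.segments
                ],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Sparky-style peak-list I/O
# ---------------------------------------------------------------------------

_ASSIGNMENT_RE = re.compile(r"^([A-Z])(\d+)N-H$")


def parse_assignment(token: str) -> tuple[str, int]:
    """Parse an amide assignment token like ``V321N-H`` into (type, number)."""
    match = _ASSIGNMENT_RE.match(token)
    if not match:
        raise FormatError(f"cannot parse assignment token {token!r}")
    return match.group(1), int(match.group(2))


def read_peak_list(source: str | Path) -> PeakList:
    """Read a Sparky-style amide peak list.

    Data rows carry: assignment token (e.g. ``V321N-H``), 15N ppm, 1H ppm,
    intensity.  A header line starting with ``Assignment`` and ``#`` comments
    are skipped.  Extra trailing columns (e.g. a volume column) are ignored.
    """
    peaks = []
    with open(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("assignment"):
                continue
            tokens = line.split()
            if len(tokens) < 4:
                raise FormatError(f"{source} line {lineno}: expected 4 fields, got {len(tokens)}")
            rtype, num = parse_assignment(tokens[0])
            try:
                pos_n, pos_h, intensity = (float(t) for t in tokens[1:4])
            except ValueError as exc:
                raise FormatError(f"{source} line {lineno}: {exc}") from exc
            peaks.append(Peak(num, rtype, position_h=pos_h, position_n=pos_n,
                              intensity=intensity))
    return PeakList(peaks)


def write_peak_list(peaks: PeakList, dest: str | Path) -> None:
    with open(dest, "w") as handle:
        handle.write("  Assignment       w1        w2    Height\n")
        for p in peaks.peaks:
            handle.write(
                f"  {p.residue_type}{p.residue_number}N-H "
                f"{p.position_n:9.4f} {p.position_h:9.4f} {p.intensity:.6e}\n"
            )


# ---------------------------------------------------------------------------
# Computation
# ---------------------------------------------------------------------------

def compute_intensity_ratios(series: TitrationSeries) -> IntensityRatioProfile:
    """Bound-over-free intensity ratios for every (residue, titration point)."""
    if len(series.reference) == 0:
        raise ValidationError("empty reference peak list")
    reference = series.reference.by_residue()
    ratios: dict[tuple[int, float], float] = {}
    for point in series.points:
        for res, peak in point.peaks.by_residue().items():
            ratios[(res, point.molar_ratio)] = peak.intensity / reference[res].intensity
    return IntensityRatioProfile(ratios)


def compute_csp(
    reference: PeakList,
    titrated: PeakList,
    n_weight: float = 0.14,
    threshold: float = 0.005,
) -> CSPProfile:
    """Weighted Euclidean CSP = sqrt(dH^2 + (n_weight * dN)^2) per shared residue.

    The 15N weight compensates for the wider 15N ppm scale (field-standard
    default 0.14); the significance threshold defaults to the 0.005 ppm
    reporting cutoff used for the 5:1 titration point.
    """
    ref = reference.by_residue()
    tit = titrated.by_residue()
    shared = sorted(set(ref) & set(tit))
    if not shared:
        raise ValidationError("no shared residues between reference and titrated lists")
    d_h = [tit[r].position_h - ref[r].position_h for r in shared]
    d_n = [tit[r].position_n - ref[r].position_n for r in shared]
    csp = [math.hypot(dh, n_weight * dn) for dh, dn in zip(d_h, d_n)]
    return CSPProfile(
        residue_numbers=shared,
        d_h=d_h,
        d_n=d_n,
        csp=csp,
        significant=[c > threshold for c in csp],
        threshold=threshold,
    )


class BindingSegmentCaller(BaseEstimator):
    """Call contiguous binding segments from an intensity-ratio profile.

    At the calling titration point nearly every residue of an IDP bound to a
    ribosome is attenuated, so site calling is relative: the baseline is the
    median ratio across residues, and a residue is site-flagged when its ratio
    is at most ``drop_factor`` times that baseline.  Flagged runs are merged
    across numbering gaps of at most ``max_gap`` residues (prolines,
    unassigned, or single noisy residues) and reported when they span at least
    ``min_length`` residues.
    """

    def __init__(
        self,
        calling_point: float | None = None,
        drop_factor: float = 0.5,
        min_length: int = 3,
        max_gap: int = 1,
    ):
        self.calling_point = calling_point
        self.drop_factor = drop_factor
        self.min_length = min_length
        self.max_gap = max_gap

    def fit(self, X: IntensityRatioProfile | None = None, y=None) -> "BindingSegmentCaller":
        if not 0 < self.drop_factor < 1:
            raise ValidationError("drop_factor must lie in (0, 1)")
        return self

    def predict(self, profile: IntensityRatioProfile) -> BindingSiteCall:
        self.fit()
        available = profile.molar_ratios()
        if not available:
            raise ValidationError("empty intensity-ratio profile")
        point = self.calling_point
        if point is None:
            point = 10.0 if 10.0 in available else available[-1]
        at_point = profile.at_point(point)
        if point not in available:
            raise ValidationError(f"no titration point at molar ratio {point}")
        if len(at_point) < 5:
            raise ValidationError(
                f"only {len(at_point)} residues with data at {point}:1; baseline unstable"
            )
        baseline = float(np.median(list(at_point.values())))
        cutoff = self.drop_factor * baseline
        flagged = sorted(r for r, v in at_point.items() if v <= cutoff)

        runs: list[list[int]] = []
        for res in flagged:
            if runs and res - runs[-1][-1] - 1 <= self.max_gap:
                runs[-1].append(res)
            else:
                runs.append([res])
        segments = [
            BindingSegment(
                start_residue=run[0],
                end_residue=run[-1],
                mean_ratio=float(np.mean([at_point[r] for r in run])),
            )
            for run in runs
            if run[-1] - run[0] + 1 >= self.min_length
        ]
        return BindingSiteCall(segments, calling_ratio_point=point, baseline_ratio=baseline)


def call_binding_segments(
    profile: IntensityRatioProfile,
    calling_point: float | None = None,
    drop_factor: float = 0.5,
    min_length: int = 3,
    max_gap: int = 1,
) -> BindingSiteCall:
    """Functional wrapper over :class:`BindingSegmentCaller`."""
    caller = BindingSegmentCaller(
        calling_point=calling_point,
        drop_factor=drop_factor,
        min_length=min_length,
        max_gap=max_gap,
    )
    return caller.fit().predict(profile)
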