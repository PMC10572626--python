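"""Far-UV circular dichroism: mean residue ellipticity and the
theta222/theta208 coiled-coil diagnostic.

A two-stranded coiled coil shows 208 and 222 nm bands of nearly equal depth
(ratio about 1.0); an isolated helix gives a ratio around 0.8; a largely
disordered chain is dominated by a deep negative band near 200 nm with a
small 222 nm signal.  The summary here reads the two band depths off the
mean-residue-ellipticity spectrum by linear interpolation and applies
configurable cutoffs to classify the spectrum qualitatively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

from oxaribo.errors import ConfigurationError, FormatError, ValidationError


@dataclass
class CDMetadata:
    concentration_mg_ml: float | None = None
    concentration_molar: float | None = None
    path_length_cm: float | None = None
    n_residues: int | None = None
    mean_residue_weight: float | None = None  # Da

    def molar_concentration(self) -> float:
        if self.concentration_molar is not None:
            return self.concentration_molar
        if (
            self.concentration_mg_ml is None
            or self.mean_residue_weight is None
            or self.n_residues is None
        ):
            raise ConfigurationError(
                "need concentration_molar, or concentration_mg_ml with "
                "mean_residue_weight and n_residues, to convert units"
            )
        molecular_weight = self.mean_residue_weight * self.n_residues  # g/mol
        return self.concentration_mg_ml / molecular_weight  # (g/L)/(g/mol) = mol/L


@dataclass
class CDSpectrum:
    """Wavelength grid (nm, strictly monotone) with ellipticity values.

    ``units`` is ``mdeg`` for raw machine output or ``mre`` after conversion
    to mean residue ellipticity (deg cm^2 dmol^-1).
    """

    wavelength: np.ndarray
    ellipticity: np.ndarray
    metadata: CDMetadata = field(default_factory=CDMetadata)
    units: Literal["mdeg", "mre"] = "mdeg"

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelength.shape != self.ellipticity.shape or self.wavelength.ndim != 1:
            raise ValidationError("wavelength and ellipticity must be 1-D and equal length")
        diffs = np.diff(self.wavelength)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError("wavelength grid must be strictly monotone")

    def ascending(self) -> "CDSpectrum":
        if self.wavelength[0] > self.wavelength[-1]:
            return replace(
                self, wavelength=self.wavelength[::-1], ellipticity=self.ellipticity[::-1]
            )
        return self

    def value_at(self, wavelength_nm: float) -> float:
        spec = self.ascending()
        if not spec.wavelength[0] <= wavelength_nm <= spec.wavelength[-1]:
            raise ValidationError(f"grid does not cover {wavelength_nm} nm")
        return float(np.interp(wavelength_nm, spec.wavelength, spec.ellipticity))


CDClass = Literal["coiled_coil", "helical", "disordered", "mixed"]


@dataclass
class CDSummary:
    theta222: float
    theta208: float
    ratio: float
    minima_wavelengths: list[float]
    classification: CDClass

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta222": self.theta222,
                "theta208": self.theta208,
                "ratio_222_208": self.ratio,
                "minima_wavelengths": self.minima_wavelengths,
                "classification": self.classification,
            },
            indent=2,
        )


def to_mean_residue_ellipticity(spec: CDSpectrum) -> CDSpectrum:
    """Convert mdeg to mean residue ellipticity:
    [theta] = theta_mdeg / (10 * c_molar * path_cm * n_residues)."""
    if spec.units == "mre":
        return spec
    meta = spec.metadata
    if meta.path_length_cm is None or meta.n_residues is None:
        raise ConfigurationError("path_length_cm and n_residues required for conversion")
    c_molar = meta.molar_concentration()
    factor = 10.0 * c_molar * meta.path_length_cm * meta.n_residues
    return replace(spec, ellipticity=spec.ellipticity / factor, units="mre")


def summarize_cd(
    spec: CDSpectrum,
    coiled_coil_ratio: float = 0.95,
    helical_ratio: float = 0.6,
    disordered_min_nm: float = 203.0,
    disordered_222_fraction: float = 0.25,
) -> CDSummary:
    """Read theta222/theta208 and classify the spectrum qualitatively.

    Classification: ``coiled_coil`` when both bands are negative and the
    ratio is at least ``coiled_coil_ratio``; ``helical`` for negative bands
    with ratio in [``helical_ratio``, ``coiled_coil_ratio``); ``disordered``
    when the global minimum lies at or below ``disordered_min_nm`` and
    |theta222| is below ``disordered_222_fraction`` of the deepest band;
    otherwise ``mixed``.  Cutoffs are heuristics anchored to canonical
    values (two-stranded coiled coil approx. 1.03, single helices approx.
    0.8) and are fully configurable.
    """
    spec = spec.ascending()
    if not (spec.wavelength[0] <= 200.0 and spec.wavelength[-1] >= 225.0):
        raise ValidationError("grid must cover at least 200-225 nm")
    theta222 = spec.value_at(222.0)
    theta208 = spec.value_at(208.0)
    floor = 1e-12 * max(1.0, float(np.max(np.abs(spec.ellipticity))))
    if abs(theta208) < floor:
        raise ValidationError("theta208 is numerically zero; ratio undefined")
    ratio = theta222 / theta208

    ell = spec.ellipticity
    interior = (np.diff(np.sign(np.diff(ell))) > 0).nonzero()[0] + 1
    minima = [float(spec.wavelength[i]) for i in interior]
    global_min_wl = float(spec.wavelength[int(np.argmin(ell))])
    deepest = float(np.min(ell))

    both_negative = theta222 < 0 and theta208 < 0
    if both_negative and ratio >= coiled_coil_ratio:
        classification: CDClass = "coiled_coil"
    elif both_negative and helical_ratio <= ratio < coiled_coil_ratio:
        classification = "helical"
    elif global_min_wl <= disordered_min_nm and abs(theta222) <= (
        disordered_222_fraction * abs(deepest)
    ):
        classification = "disordered"
    else:
        classification = "mixed"
    return CDSummary(
        theta222=theta222,
        theta208=theta208,
        ratio=float(ratio),
        minima_wavelengths=minima,
        classification=classification,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_KEYS = {
    "concentration_mg_ml": float,
    "concentration_molar": float,
    "path_length_cm": float,
    "n_residues": int,
    "mean_residue_weight": float,
}


def read_cd_spectrum(source: str | Path) -> CDSpectrum:
    """Read a CD CSV: ``# key = value`` metadata lines, then
    ``wavelength_nm,ellipticity_mdeg`` header and data rows."""
    meta = CDMetadata()
    wl, ell = [], []
    with open(source) as handle:
        header_seen = False
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, value = (t.strip() for t in body.split("=", 1))
                    if key in _META_KEYS:
                        setattr(meta, key, _META_KEYS[key](value))
                continue
            if not header_seen:
                if line.replace(" ", "") != "wavelength_nm,ellipticity_mdeg":
                    raise FormatError(
                        f"{source} line {lineno}: expected header "
                        "'wavelength_nm,ellipticity_mdeg'"
                    )
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != 2:
                raise FormatError(f"{source} line {lineno}: expected 2 fields")
            try:
                wl.append(float(fields[0]))
                ell.append(float(fields[1]))
            except ValueError as exc:
                raise FormatError(f"{source} line {lineno}: {exc}") from exc
    return CDSpectrum(np.array(wl), np.array(ell), metadata=meta)


def write_cd_spectrum(spec: CDSpectrum, dest: str | Path) -> None:
    meta = spec.metadata
    with open(dest, "w") as handle:
        for key in _META_KEYS:
            value = getattr(meta, key)
            if value is not None:
                handle.write(f"# {key} = {value:g}\n")
        handle.write("wavelength_nm,ellipticity_mdeg\n")
        for w, e in zip(spec.wavelength, spec.ellipticity):
            handle.write(f"{w:.1f},{e:.6g}\n")
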