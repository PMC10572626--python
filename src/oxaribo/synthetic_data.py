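"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure of a residue-level NMR/MST
study of an 83-residue disordered domain (numbered 320-402) binding a 70S
ribosome:

- an assigned backbone shift table whose expected secondary shift is
  3.0 ppm times a per-residue helix propensity (planted transient helix);
- an HSQC titration series whose per-residue intensity ratios drop with the
  bound fraction, amplified at planted binding segments;
- an MST dose-response curve from the quadratic ligand-depletion model;
- a far-UV CD spectrum from an analytic Gaussian band basis.

The intensity model is deliberately phenomenological: at a 10:1
protein:ribosome ratio only ~10% of the protein is bound, yet on-site peaks
lose ~80% of their intensity in the real experiment because exchange with a
slowly tumbling 2.5-MDa complex broadens them far beyond their bound
population.  The generator mimics that with linear amplification factors
(``k_global`` for the uniform loss, ``k_site`` extra at binding sites); it is
a stand-in for exchange broadening, not a physical relaxation model.

Randomness contract: all draws come from NumPy ``default_rng`` (PCG64) seeded
as ``[seed, stream]`` with a fixed stream id per generator, so outputs are
bit-for-bit reproducible for a fixed seed on any platform.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from oxaribo.binding_fit import DoseResponse, fraction_bound, write_dose_response
from oxaribo.cd_ellipticity import CDMetadata, CDSpectrum, write_cd_spectrum
from oxaribo.errors import ValidationError
from oxaribo.random_coil import AA1, RandomCoilTable, wishart_1995
from oxaribo.secondary_shifts import ShiftEntry, ShiftTable, write_shift_table
from oxaribo.titration_mapping import (
    Peak,
    PeakList,
    TitrationPoint,
    TitrationSeries,
    write_peak_list,
)

_STREAM_SHIFTS = 0
_STREAM_AMIDE = 1
_STREAM_REF_INTENSITY = 2
_STREAM_TITRATION = 3
_STREAM_MST = 4

# The 15-point two-fold ribosome dilution series of the MST assay, in nM.
MST_CONCENTRATIONS_NM = (
    1.21, 2.43, 4.87, 9.75, 19.5, 39.0, 78.0, 156.0, 312.0, 625.0,
    1250.0, 2500.0, 5000.0, 10000.0, 20000.0,
)

# Residues of the domain whose identities are fixed by the study design
# (contact sites, helix boundaries, assignment landmarks).
_NAMED_RESIDUES = {
    320: "W", 321: "V", 322: "R", 323: "S", 325: "L", 327: "I", 328: "K",
    330: "V", 341: "S", 342: "P", 348: "I", 349: "F", 350: "Q", 353: "K",
    355: "N", 359: "A", 365: "R", 370: "Q", 373: "E", 378: "E", 379: "S",
    382: "E", 385: "Q", 387: "S", 388: "K", 398: "I", 399: "N", 402: "K",
}
# Two invented prolines so the chain has 3 prolines and 80 non-proline amides.
_EXTRA_PROLINES = {335: "P", 394: "P"}

# 15 amide-unassigned positions (19% of 80 non-proline residues stay
# unassigned, matching a 65/80 = 81% assignment yield); includes the five
# landmark unassigned residues and ten more spread so no two are adjacent.
DEFAULT_UNASSIGNED = (
    323, 331, 333, 337, 344, 350, 358, 366, 372, 379, 386, 391, 396, 399, 402,
)

FIRST_RESIDUE = 320
LAST_RESIDUE = 402

HELIX_REGION = (342, 385)
BINDING_SEGMENTS = ((321, 327), (348, 370))


def _build_sequence() -> str:
    seq = []
    for pos in range(FIRST_RESIDUE, LAST_RESIDUE + 1):
        if pos in _NAMED_RESIDUES:
            seq.append(_NAMED_RESIDUES[pos])
        elif pos in _EXTRA_PROLINES:
            seq.append(_EXTRA_PROLINES[pos])
        else:
            seq.append("A" if pos % 2 == 0 else "S")
    return "".join(seq)


@dataclass
class SyntheticStudyConfig:
    """Ground-truth parameters for all generators.

    ``helix_propensity`` and ``binding_profile`` carry one value in [0, 1]
    per sequence residue.  Concentrations: ``kd_uM``, ``protein_total_uM``
    and ``mst_ligand_total_uM`` in uM; ``mst_concentrations_nM`` in nM.
    """

    sequence: str
    first_residue: int
    helix_propensity: np.ndarray
    binding_profile: np.ndarray
    kd_uM: float
    protein_total_uM: float
    molar_ratios: tuple[float, ...]
    mst_ligand_total_uM: float
    mst_concentrations_nM: tuple[float, ...]
    mst_amplitude: float
    mst_noise_fraction: float
    k_global: float
    k_site: float
    shift_noise_sd: float
    intensity_noise_sd: float
    bound_dh_ppm: float
    bound_dn_ppm: float
    unassigned_residues: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        self.helix_propensity = np.asarray(self.helix_propensity, dtype=float)
        self.binding_profile = np.asarray(self.binding_profile, dtype=float)
        n = len(self.sequence)
        if any(aa not in AA1 for aa in self.sequence):
            raise ValidationError("sequence contains non-standard residue codes")
        for name, profile in (
            ("helix_propensity", self.helix_propensity),
            ("binding_profile", self.binding_profile),
        ):
            if profile.shape != (n,):
                raise ValidationError(f"{name} must have one value per residue")
            if np.any((profile < 0) | (profile > 1)):
                raise ValidationError(f"{name} values must lie in [0, 1]")
        for name in (
            "kd_uM", "protein_total_uM", "mst_ligand_total_uM", "mst_amplitude",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in (
            "mst_noise_fraction", "k_global", "k_site", "shift_noise_sd",
            "intensity_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if any(r <= 0 for r in self.molar_ratios):
            raise ValidationError("molar ratios must be > 0")
        if list(self.molar_ratios) != sorted(set(self.molar_ratios), reverse=True):
            raise ValidationError("molar ratios must be unique and strictly decreasing")
        if np.any(np.diff(self.mst_concentrations_nM) <= 0):
            raise ValidationError("MST concentrations must be strictly increasing")

    # -- residue helpers ----------------------------------------------------

    def residue_numbers(self) -> range:
        return range(self.first_residue, self.first_residue + len(self.sequence))

    def residue_type(self, number: int) -> str:
        return self.sequence[number - self.first_residue]

    def propensity(self, number: int) -> float:
        return float(self.helix_propensity[number - self.first_residue])

    def binding(self, number: int) -> float:
        return float(self.binding_profile[number - self.first_residue])

    def amide_residues(self) -> list[int]:
        """Residues visible in amide peak lists: non-proline and assigned."""
        return [
            r
            for r in self.residue_numbers()
            if self.residue_type(r) != "P" and r not in self.unassigned_residues
        ]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        data = asdict(self)
        data["helix_propensity"] = [float(x) for x in self.helix_propensity]
        data["binding_profile"] = [float(x) for x in self.binding_profile]
        data["molar_ratios"] = list(self.molar_ratios)
        data["mst_concentrations_nM"] = list(self.mst_concentrations_nM)
        data["unassigned_residues"] = list(self.unassigned_residues)
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticStudyConfig":
        data = dict(data)
        for key in ("molar_ratios", "mst_concentrations_nM", "unassigned_residues"):
            data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, dest: str | Path) -> None:
        with open(dest, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SyntheticStudyConfig":
        with open(source) as handle:
            return cls.from_dict(yaml.safe_load(handle))


def default_oxa1_config(seed: int = 20230928) -> SyntheticStudyConfig:
    """The default study fixture: an 83-residue Oxa1-CTD-like chain (numbered
    320-402) with a transient helix planted on 342-385 at propensity 0.5 and
    binding sites on 321-327 and 348-370, Kd 0.45 uM, a 45 uM titration at
    ratios 400/100/10/5:1 and a 20 uM, 15-point MST series.

    The filler positions of the sequence are Ala/Ser: this is NOT the true
    protein sequence, only a fixture honoring every landmark residue identity.
    """
    sequence = _build_sequence()
    n = len(sequence)
    helix = np.full(n, 0.05)
    helix[HELIX_REGION[0] - FIRST_RESIDUE: HELIX_REGION[1] - FIRST_RESIDUE + 1] = 0.5
    binding = np.zeros(n)
    for start, end in BINDING_SEGMENTS:
        binding[start - FIRST_RESIDUE: end - FIRST_RESIDUE + 1] = 1.0
    return SyntheticStudyConfig(
        sequence=sequence,
        first_residue=FIRST_RESIDUE,
        helix_propensity=helix,
        binding_profile=binding,
        kd_uM=0.45,
        protein_total_uM=45.0,
        molar_ratios=(400.0, 100.0, 10.0, 5.0),
        mst_ligand_total_uM=20.0,
        mst_concentrations_nM=MST_CONCENTRATIONS_NM,
        mst_amplitude=1.0,
        mst_noise_fraction=0.01,
        k_global=5.0,
        k_site=3.0,
        shift_noise_sd=0.15,
        intensity_noise_sd=0.05,
        bound_dh_ppm=0.02,
        bound_dn_ppm=0.1,
        unassigned_residues=DEFAULT_UNASSIGNED,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_shift_table(
    config: SyntheticStudyConfig, refs: RandomCoilTable | None = None
) -> ShiftTable:
    """Assigned backbone shift table with planted helix propensity.

    Per assigned residue: dCA = CA_rc + 2.4 p + eps, dCB = CB_rc - 0.6 p +
    eps', eps ~ N(0, shift_noise_sd), so the expected secondary shift
    (ddCA - ddCB) is 3.0 p ppm.  Prolines carry CA/CB but no H/N; amide-
    unassigned residues are dropped entirely.
    """
    if refs is None:
        refs = wishart_1995()
    rng = config._rng(_STREAM_SHIFTS)
    amide = _amide_positions(config)
    entries = []
    for number in config.residue_numbers():
        if number in config.unassigned_residues:
            continue
        rtype = config.residue_type(number)
        p = config.propensity(number)
        shifts: dict[str, float] = {
            "CA": refs.ca[rtype] + 2.4 * p + rng.normal(0.0, config.shift_noise_sd)
        }
        if rtype != "G":
            shifts["CB"] = (
                refs.cb[rtype] - 0.6 * p + rng.normal(0.0, config.shift_noise_sd)
            )
        if rtype != "P":
            shifts["H"], shifts["N"] = amide[number]
        entries.append(ShiftEntry(number, rtype, shifts))
    return ShiftTable(entries)


def _amide_positions(config: SyntheticStudyConfig) -> dict[int, tuple[float, float]]:
    """Free-state amide peak positions, shared by the shift table and the
    titration reference: 1H in the narrow 7.8-8.5 ppm window typical of a
    disordered chain, 15N spread over 108-130 ppm."""
    rng = config._rng(_STREAM_AMIDE)
    positions = {}
    for number in config.residue_numbers():
        h = float(rng.uniform(7.8, 8.5))
        n15 = float(rng.uniform(108.0, 130.0))
        if config.residue_type(number) != "P":
            positions[number] = (h, n15)
    return positions


def gen_titration_series(config: SyntheticStudyConfig) -> TitrationSeries:
    """Titration series with binding-segment-dependent intensity loss.

    At each molar ratio r the ribosome concentration is A = protein_total / r
    and the bound fraction f = FB(A; protein_total, Kd).  The expected
    intensity ratio of residue i is rho_i = max(0, 1 - f (k_global + k_site
    b_i)); observed intensities are the reference intensities times rho_i
    times multiplicative lognormal noise exp(N(0, intensity_noise_sd)).
    Peaks with rho_i <= 0 are dropped (broadened beyond detection).  Peak
    positions drift by f b_i (bound_dh_ppm, bound_dn_ppm), the fast-exchange
    CSP signature.
    """
    amide = _amide_positions(config)
    visible = config.amide_residues()
    rng_ref = config._rng(_STREAM_REF_INTENSITY)
    ref_intensity = {
        r: float(1e6 * np.exp(rng_ref.normal(0.0, 0.2))) for r in visible
    }
    reference = PeakList(
        [
            Peak(r, config.residue_type(r), amide[r][0], amide[r][1], ref_intensity[r])
            for r in visible
        ]
    )
    rng = config._rng(_STREAM_TITRATION)
    points = []
    for ratio in config.molar_ratios:
        a_uM = config.protein_total_uM / ratio
        f = fraction_bound(a_uM, config.protein_total_uM, config.kd_uM)
        peaks = []
        for r in visible:
            rho = 1.0 - f * (config.k_global + config.k_site * config.binding(r))
            noise = float(np.exp(rng.normal(0.0, config.intensity_noise_sd)))
            if rho <= 0.0:
                continue
            drift = f * config.binding(r)
            peaks.append(
                Peak(
                    r,
                    config.residue_type(r),
                    position_h=amide[r][0] + drift * config.bound_dh_ppm,
                    position_n=amide[r][1] + drift * config.bound_dn_ppm,
                    intensity=ref_intensity[r] * rho * noise,
                )
            )
        points.append(TitrationPoint(molar_ratio=ratio, peaks=PeakList(peaks)))
    return TitrationSeries(
        reference=reference, points=points, protein_total=config.protein_total_uM
    )


def gen_mst_curve(config: SyntheticStudyConfig) -> DoseResponse:
    """MST dose-response from the depletion model with multiplicative noise:
    response_i = amplitude * FB(A_i; B, Kd) * (1 + N(0, noise_fraction))."""
    rng = config._rng(_STREAM_MST)
    a_nM = np.asarray(config.mst_concentrations_nM, dtype=float)
    fb = fraction_bound(a_nM, config.mst_ligand_total_uM * 1000.0, config.kd_uM * 1000.0)
    noise = rng.normal(0.0, config.mst_noise_fraction, size=a_nM.size)
    return DoseResponse(
        titrant_conc=a_nM,
        response=config.mst_amplitude * fb * (1.0 + noise),
        ligand_total=config.mst_ligand_total_uM,
    )


# Gaussian band bases (mean residue ellipticity, deg cm^2 dmol^-1).  An
# analytic stand-in for helix and coil far-UV CD shapes, not a physical model:
# helix = positive 193 band, equal-depth negative 208/222 bands (so a pure
# "helix bundle" scores a coiled-coil-like ratio near 1); coil = deep negative
# 200 band with a weak positive tail near 222.
_HELIX_BANDS = ((193.0, 5.0, 70000.0), (208.0, 6.0, -33000.0), (222.0, 6.0, -33000.0))
_COIL_BANDS = ((200.0, 7.0, -30000.0), (222.0, 10.0, 2000.0))


def _bands(wavelength: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(wavelength)
    for center, width, amplitude in bands:
        out += amplitude * np.exp(-((wavelength - center) ** 2) / (2.0 * width**2))
    return out


def gen_cd_spectrum(
    helix_fraction: float,
    config: SyntheticStudyConfig,
    concentration_mg_ml: float = 0.2,
    path_length_cm: float = 0.1,
    mean_residue_weight: float = 110.0,
) -> CDSpectrum:
    """Far-UV CD spectrum (190-260 nm, 1 nm steps) as a linear mix of the
    helix and coil band bases, returned in raw mdeg with full metadata."""
    if not 0.0 <= helix_fraction <= 1.0:
        raise ValidationError("helix_fraction must lie in [0, 1]")
    wavelength = np.arange(190.0, 261.0, 1.0)
    mre = helix_fraction * _bands(wavelength, _HELIX_BANDS) + (
        1.0 - helix_fraction
    ) * _bands(wavelength, _COIL_BANDS)
    n_residues = len(config.sequence)
    meta = CDMetadata(
        concentration_mg_ml=concentration_mg_ml,
        path_length_cm=path_length_cm,
        n_residues=n_residues,
        mean_residue_weight=mean_residue_weight,
    )
    c_molar = meta.molar_concentration()
    mdeg = mre * 10.0 * c_molar * path_length_cm * n_residues
    return CDSpectrum(wavelength, mdeg, metadata=meta, units="mdeg")


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def write_synthetic_inputs(config: SyntheticStudyConfig, outdir: str | Path) -> dict[str, Path]:
    """Write one complete synthetic input set in every on-disk format the
    readers accept; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = gen_shift_table(config)
    paths["shift_table_tsv"] = outdir / "shifts.tsv"
    write_shift_table(table, paths["shift_table_tsv"], dialect="tsv")
    paths["shift_table_star"] = outdir / "shifts.str"
    write_shift_table(table, paths["shift_table_star"], dialect="nmrstar")

    series = gen_titration_series(config)
    paths["peaks_reference"] = outdir / "peaks_reference.list"
    write_peak_list(series.reference, paths["peaks_reference"])
    for point in series.points:
        key = f"peaks_{point.molar_ratio:g}to1"
        paths[key] = outdir / f"{key}.list"
        write_peak_list(point.peaks, paths[key])

    paths["mst_csv"] = outdir / "mst.csv"
    write_dose_response(gen_mst_curve(config), paths["mst_csv"])

    paths["cd_csv"] = outdir / "cd.csv"
    helix_region_fraction = float(np.mean(config.helix_propensity))
    write_cd_spectrum(gen_cd_spectrum(helix_region_fraction, config), paths["cd_csv"])

    paths["config_yaml"] = outdir / "config.yaml"
    config.to_yaml(paths["config_yaml"])
    return paths
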