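"""Pipeline orchestration: run the analysis stages in dependency order and
emit a reproducible report bundle.

Stages (each optional; a partial config runs a partial pipeline):

- ``shifts``     secondary chemical shifts -> segment classification
- ``titration``  intensity ratios -> CSP -> binding-segment call
- ``mst``        dose-response -> depletion-model Kd fit
- ``cd``         mean residue ellipticity -> theta222/theta208 summary

Every input is either a path or generated from the synthetic study config,
and a run manifest (config hash, seed, package versions) plus the effective
configuration are always written, so deterministic stages re-run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

import oxaribo
from oxaribo import synthetic_data
from oxaribo.binding_fit import (
    BindingFitResult,
    DoseResponse,
    bootstrap_ci,
    fit_kd,
    read_dose_response,
)
from oxaribo.cd_ellipticity import (
    CDSummary,
    read_cd_spectrum,
    summarize_cd,
    to_mean_residue_ellipticity,
)
from oxaribo.errors import ConfigurationError, ValidationError
from oxaribo.secondary_shifts import (
    SegmentClassifier,
    compute_secondary_shifts,
    read_shift_table,
    write_profile,
)
from oxaribo.titration_mapping import (
    BindingSegmentCaller,
    BindingSiteCall,
    CSPProfile,
    IntensityRatioProfile,
    TitrationPoint,
    TitrationSeries,
    compute_csp,
    compute_intensity_ratios,
    read_peak_list,
)


@dataclass
class PipelineConfig:
    """Validated stage configuration.

    Each stage block is a plain dict (absent block = stage skipped).  When a
    stage has no input path and ``synthetic`` is enabled, its input is
    generated from :func:`oxaribo.synthetic_data.default_oxa1_config` with
    this config's seed.
    """

    outdir: str = "oxaribo_out"
    seed: int = 20230928
    synthetic: bool = True
    plots: bool = False
    shifts: dict | None = None
    titration: dict | None = None
    mst: dict | None = None
    cd: dict | None = None

    _KNOWN = {
        "shifts": {
            "input", "dialect", "stable", "transient", "coil", "window",
            "min_length", "include_ca_only", "max_missing_gap", "exclude_below",
            "use_neighbor_corrections", "global_offset",
        },
        "titration": {
            "reference", "points", "protein_total_uM", "calling_point",
            "drop_factor", "min_length", "max_gap", "n_weight", "csp_threshold",
            "csp_point",
        },
        "mst": {"input", "ligand_total_uM", "fit_offset", "init_kd", "bootstrap",
                "n_boot", "ci_level"},
        "cd": {"inputs", "helix_fraction"},
    }

    def __post_init__(self) -> None:
        for stage, known in self._KNOWN.items():
            block = getattr(self, stage)
            if block is None:
                continue
            unknown = set(block) - known
            if unknown:
                raise ConfigurationError(f"{stage}: unknown keys {sorted(unknown)}")
        if self.shifts is not None:
            stable = self.shifts.get("stable", 2.0)
            transient = self.shifts.get("transient", 0.5)
            coil = self.shifts.get("coil", 0.5)
            if not stable > transient > 0 or coil <= 0:
                raise ValidationError(
                    "shift thresholds must satisfy stable > transient > 0 and coil > 0"
                )
            window = self.shifts.get("window", 5)
            if window < 1 or window % 2 == 0:
                raise ValidationError("shifts window must be an odd integer >= 1")
        if self.titration is not None:
            drop = self.titration.get("drop_factor", 0.5)
            if not 0 < drop < 1:
                raise ValidationError("titration drop_factor must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        with open(source) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)


@dataclass
class ReportBundle:
    """Outputs of one pipeline run: file artifacts plus in-memory results."""

    outdir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    segments: list | None = None
    ratio_profile: IntensityRatioProfile | None = None
    csp_profile: CSPProfile | None = None
    binding_call: BindingSiteCall | None = None
    kd_fit: BindingFitResult | None = None
    cd_summaries: list[CDSummary] | None = None


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=outdir)
    syn = (
        synthetic_data.default_oxa1_config(seed=config.seed)
        if config.synthetic
        else None
    )

    with open(outdir / "effective_config.yaml", "w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=False)
    bundle.outputs["effective_config"] = outdir / "effective_config.yaml"

    stage = "none"
    try:
        if config.shifts is not None:
            stage = "shifts"
            _run_shifts(config, syn, bundle)
        if config.titration is not None:
            stage = "titration"
            _run_titration(config, syn, bundle)
        if config.mst is not None:
            stage = "mst"
            _run_mst(config, syn, bundle)
        if config.cd is not None:
            stage = "cd"
            _run_cd(config, syn, bundle)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise type(exc)(f"stage {stage}: {exc}") from exc

    bundle.manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "oxaribo": oxaribo.__version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": {k: str(v) for k, v in bundle.outputs.items()},
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(bundle.manifest, handle, indent=2)
    bundle.outputs["manifest"] = outdir / "manifest.json"

    if config.plots:
        from oxaribo import plots

        bundle.outputs.update(plots.render_bundle_plots(bundle))
    return bundle


def _run_shifts(config: PipelineConfig, syn, bundle: ReportBundle) -> None:
    opts = config.shifts or {}
    if "input" in opts:
        table = read_shift_table(opts["input"], dialect=opts.get("dialect", "tsv"))
    elif syn is not None:
        table = synthetic_data.gen_shift_table(syn)
    else:
        raise ConfigurationError("shifts stage has no input and synthetic is off")
    profile = compute_secondary_shifts(
        table,
        use_neighbor_corrections=opts.get("use_neighbor_corrections", False),
        global_offset=opts.get("global_offset", 0.0),
    )
    clf = SegmentClassifier(
        stable=opts.get("stable", 2.0),
        transient=opts.get("transient", 0.5),
        coil=opts.get("coil", 0.5),
        window=opts.get("window", 5),
        min_length=opts.get("min_length", 4),
        include_ca_only=opts.get("include_ca_only", False),
        max_missing_gap=opts.get("max_missing_gap", 1),
        exclude_below=opts.get("exclude_below"),
    )
    segments = clf.fit().predict(profile)
    bundle.segments = segments
    out = bundle.outdir / "secondary_shifts.tsv"
    write_profile(profile, segments, out)
    bundle.outputs["secondary_shifts"] = out
    seg_json = bundle.outdir / "segments.json"
    with open(seg_json, "w") as handle:
        json.dump(
            [dataclasses.asdict(s) for s in segments], handle, indent=2
        )
    bundle.outputs["segments"] = seg_json


def _load_series(opts: dict, syn) -> TitrationSeries:
    if "reference" in opts and "points" in opts:
        reference = read_peak_list(opts["reference"])
        points = [
            TitrationPoint(molar_ratio=float(ratio), peaks=read_peak_list(path))
            for ratio, path in sorted(
                ((float(r), p) for r, p in dict(opts["points"]).items()),
                key=lambda item: -item[0]
            )
        ]
        return TitrationSeries(
            reference=reference,
            points=points,
            protein_total=opts.get("protein_total_uM", 45.0),
        )
    if syn is not None:
        return synthetic_data.gen_titration_series(syn)
    raise ConfigurationError("titration stage has no input and synthetic is off")


def _run_titration(config: PipelineConfig, syn, bundle: ReportBundle) -> None:
    opts = config.titration or {}
    series = _load_series(opts, syn)
    profile = compute_intensity_ratios(series)
    bundle.ratio_profile = profile
    out = bundle.outdir / "intensity_ratios.tsv"
    profile.to_frame().to_csv(out, sep="\t", index=False, float_format="%.5f")
    bundle.outputs["intensity_ratios"] = out

    ratios = [p.molar_ratio for p in series.points]
    csp_point = opts.get("csp_point", min(ratios))
    titrated = next(p.peaks for p in series.points if p.molar_ratio == csp_point)
    csp = compute_csp(
        series.reference,
        titrated,
        n_weight=opts.get("n_weight", 0.14),
        threshold=opts.get("csp_threshold", 0.005),
    )
    bundle.csp_profile = csp
    out = bundle.outdir / "csp.tsv"
    csp.to_frame().to_csv(out, sep="\t", index=False, float_format="%.6f")
    bundle.outputs["csp"] = out

    caller = BindingSegmentCaller(
        calling_point=opts.get("calling_point"),
        drop_factor=opts.get("drop_factor", 0.5),
        min_length=opts.get("min_length", 3),
        max_gap=opts.get("max_gap", 1),
    )
    call = caller.fit().predict(profile)
    bundle.binding_call = call
    out = bundle.outdir / "binding_call.json"
    out.write_text(call.to_json() + "\n")
    bundle.outputs["binding_call"] = out


def _run_mst(config: PipelineConfig, syn, bundle: ReportBundle) -> None:
    opts = config.mst or {}
    if "input" in opts:
        data = read_dose_response(opts["input"])
        if "ligand_total_uM" in opts:
            data = DoseResponse(
                data.titrant_conc, data.response, ligand_total=opts["ligand_total_uM"]
            )
    elif syn is not None:
        data = synthetic_data.gen_mst_curve(syn)
    else:
        raise ConfigurationError("mst stage has no input and synthetic is off")
    fit = fit_kd(
        data,
        fit_offset=opts.get("fit_offset", False),
        init_kd=opts.get("init_kd"),
    )
    if opts.get("bootstrap", False) and fit.converged:
        fit.ci = bootstrap_ci(
            data,
            fit,
            n_boot=opts.get("n_boot", 200),
            level=opts.get("ci_level", 0.95),
            seed=config.seed,
        )
    bundle.kd_fit = fit
    bundle._mst_data = data  # kept for plotting
    out = bundle.outdir / "kd_fit.json"
    out.write_text(fit.to_json() + "\n")
    bundle.outputs["kd_fit"] = out


def _run_cd(config: PipelineConfig, syn, bundle: ReportBundle) -> None:
    opts = config.cd or {}
    if "inputs" in opts:
        spectra = [read_cd_spectrum(path) for path in opts["inputs"]]
    elif syn is not None:
        spectra = [
            synthetic_data.gen_cd_spectrum(opts.get("helix_fraction", 0.3), syn)
        ]
    else:
        raise ConfigurationError("cd stage has no input and synthetic is off")
    summaries = [summarize_cd(to_mean_residue_ellipticity(s)) for s in spectra]
    bundle.cd_summaries = summaries
    out = bundle.outdir / "cd_summary.json"
    out.write_text(
        json.dumps([json.loads(s.to_json()) for s in summaries], indent=2) + "\n"
    )
    bundle.outputs["cd_summary"] = out
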