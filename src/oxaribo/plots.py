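"""Optional plot artifacts mirroring the standard figures of a titration
study: secondary-shift bar profile, per-point intensity-ratio profiles, CSP
profile with its significance threshold, and the dose-response curve with
the fitted depletion model.  Plots are outputs only; no computation reads
them back."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from oxaribo.binding_fit import fraction_bound


def render_bundle_plots(bundle) -> dict[str, Path]:
    out: dict[str, Path] = {}
    if "secondary_shifts" in bundle.outputs:
        out["plot_secondary_shifts"] = _plot_shifts(bundle)
    if bundle.ratio_profile is not None:
        out["plot_intensity_ratios"] = _plot_ratios(bundle)
    if bundle.csp_profile is not None:
        out["plot_csp"] = _plot_csp(bundle)
    if bundle.kd_fit is not None and getattr(bundle, "_mst_data", None) is not None:
        out["plot_kd_fit"] = _plot_fit(bundle)
    return out


def _plot_shifts(bundle) -> Path:
    frame = pd.read_csv(bundle.outputs["secondary_shifts"], sep="\t")
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(frame["residue_number"], frame["delta_ppm"], width=0.8, color="steelblue")
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel("residue")
    ax.set_ylabel(r"$\Delta\delta C\alpha - \Delta\delta C\beta$ (ppm)")
    path = bundle.outdir / "secondary_shifts.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def _plot_ratios(bundle) -> Path:
    frame = bundle.ratio_profile.to_frame()
    fig, ax = plt.subplots(figsize=(8, 3))
    for ratio, sub in frame.groupby("molar_ratio"):
        ax.plot(sub["residue_number"], sub["ratio"], ".-", ms=3, lw=0.6,
                label=f"{ratio:g}:1")
    ax.axhline(1.0, color="black", ls="--", lw=0.5)
    ax.set_xlabel("residue")
    ax.set_ylabel("I / I$_0$")
    ax.legend(fontsize=7)
    path = bundle.outdir / "intensity_ratios.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def _plot_csp(bundle) -> Path:
    csp = bundle.csp_profile
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(csp.residue_numbers, csp.csp, width=0.8, color="indianred")
    ax.axhline(csp.threshold, color="black", ls="--", lw=0.8)
    ax.set_xlabel("residue")
    ax.set_ylabel("CSP (ppm)")
    path = bundle.outdir / "csp.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def _plot_fit(bundle) -> Path:
    data = bundle._mst_data
    fit = bundle.kd_fit
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.semilogx(data.titrant_conc, data.response, "o", ms=4, label="data")
    grid = np.geomspace(data.titrant_conc[0], data.titrant_conc[-1], 200)
    model = fit.offset + fit.amplitude * fraction_bound(
        grid, data.ligand_total * 1000.0, fit.kd * 1000.0
    )
    ax.semilogx(grid, model, "-", label=f"fit, Kd = {fit.kd:.2f} uM")
    ax.set_xlabel("titrant (nM)")
    ax.set_ylabel(r"1 - F$_i$/F$_{norm}$")
    ax.legend(fontsize=8)
    path = bundle.outdir / "kd_fit.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
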