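# oxaribo

Residue-level characterization of an intrinsically disordered protein (IDP)
domain and its ribosome interaction, packaged as a tested, reusable pipeline.
The motivating system is the C-terminal domain of the yeast mitochondrial
insertase Oxa1 (Oxa1-CTD, residues W320–K402), a disordered, positively
charged tail that tethers the ribosome during co-translational membrane
insertion — but every stage works on any assigned backbone shift table, HSQC
titration series, MST dose–response table or far-UV CD spectrum in the plain
text formats described below.

It is written for NMR/biophysics practitioners who have finished peak
assignment and want the downstream numbers: where the transient helix is,
which residues contact the partner, and how tight the binding is.

## What it computes

**Secondary chemical shifts** (`oxaribo.secondary_shifts`). For each residue
with observed Cα/Cβ shifts,

    Δδ = (δCαobs − δCαrc) − (δCβobs − δCβrc)

against a random-coil reference set (built-in: Wishart 1995; user tables
accepted). Consecutive values near +3 ppm mean a well-formed α-helix,
roughly +1 to +2 ppm a transient (partially populated) helix, near 0 random
coil, negative values extended structure. A centered running mean (window 5)
is cut at configurable thresholds (stable ≥ 2.0 ppm, transient ≥ 0.5 ppm,
extended ≤ −0.5 ppm) and maximal runs ≥ 4 residues become segments.

**Titration mapping** (`oxaribo.titration_mapping`). From Sparky-style peak
lists at decreasing protein:ribosome molar ratios: per-residue intensity
ratios I/I₀; chemical shift perturbations CSP = √(ΔδH² + (0.14·ΔδN)²);
and a binding-segment caller that flags residues whose ratio falls below
half of the median ratio at the calling point (default the 10:1 spectrum) —
relative calling matters because a huge, slowly tumbling partner attenuates
*every* amide via exchange broadening, and the binding site only more so.

**Ligand-depletion Kd fit** (`oxaribo.binding_fit`). MST dose–response
curves (1 − Fi/Fnorm vs titrant concentration A, labelled protein B fixed)
are fit with the exact two-component mass-action (quadratic) isotherm

    FB = ([A]+[B]+Kd − √(([A]+[B]+Kd)² − 4[A][B])) / (2[B])

as response = offset + amplitude · FB(A; B, Kd), by bounded nonlinear least
squares (`KdRegressor`, a scikit-learn-style estimator), with a residual
bootstrap for Kd confidence intervals. The quadratic form is required when
B is comparable to or above Kd (ligand depletion), the regime of a 20 µM
labelled protein binding a sub-µM-Kd partner.

**CD summary** (`oxaribo.cd_ellipticity`). Mean residue ellipticity
conversion and the θ222/θ208 coiled-coil diagnostic (≈1.0 for two-stranded
coiled coils, ≈0.8 for isolated helices, low for disordered chains), with a
qualitative classification.

**Synthetic study generator** (`oxaribo.synthetic_data`). Seeded,
bit-reproducible generators produce every input above with the statistical
structure the analysis assumes (planted transient helix, planted binding
segments with amplified intensity loss, depletion-model MST curve, Gaussian
band-basis CD spectra), so the full pipeline is testable offline.

## Worked example

Run the whole pipeline on the default synthetic study (83-residue chain
numbered 320–402, helix propensity 0.5 planted on 342–385, binding sites
321–327 and 348–370, Kd 0.45 µM):

```
$ oxaribo run --out demo --no-plots
```

`demo/segments.json` (secondary-structure call; mean Δδ in ppm):

```
coil             320–340   mean_delta 0.23
transient_helix  341–387   mean_delta 1.46
coil             388–401   mean_delta 0.24
```

The smoothed Δδ profile sits near 1.5 ppm — a half-populated helix — over
the planted region, and near zero in the flanks.

`demo/binding_call.json` (intensity-ratio call at the 10:1 point):

```
baseline_ratio 0.488
segment 321–327  mean_ratio 0.202
segment 348–370  mean_ratio 0.211
```

Off-site residues keep ≈49% of their free intensity (the uniform exchange
broadening), site residues only ≈21% (the ~80% loss contrast), and exactly
the two planted contact segments are called.

`demo/kd_fit.json`:

```
kd_uM 0.532   amplitude 1.008   rss 9.2e-06   converged true
```

The fit recovers the 0.45 µM ground truth to within the scatter that 1%
multiplicative noise allows in this depletion-dominated regime (B/Kd ≈ 44;
see `docs/methods.md`).

Individual stages are also exposed: `oxaribo simulate`, `oxaribo shifts`,
`oxaribo titrate`, `oxaribo fitkd`, `oxaribo cd`, `oxaribo report`, or the
library functions they wrap.

## File formats

- Shift tables: TSV (`residue_number  residue_type  nucleus  shift_ppm`) or
  an NMR-STAR v3 assigned-chemical-shift loop.
- Peak lists: Sparky-style (`V321N-H  120.5  8.20  1.0e6`).
- MST: CSV with `# ligand_total_uM = 20` metadata then `conc_nM,response`.
- CD: CSV with `# concentration_mg_ml = ...` metadata then
  `wavelength_nm,ellipticity_mdeg`.

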