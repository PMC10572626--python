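# Methods

This note records the models, the defaults and their rationale, the
numerical choices, and what the synthetic-data generators do and do not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Secondary chemical shifts

The per-residue statistic is the Cα−Cβ difference form of the secondary
chemical shift, Δδ = (δCα,obs − δCα,rc) − (δCβ,obs − δCβ,rc). Using the
difference of the two carbons doubles the helix/strand contrast and cancels
any global ¹³C referencing offset (a `global_offset` re-referencing hook
exists anyway, default 0; no reference-compound correction is attempted).

Random-coil baselines are the Wishart et al. (1995) Ac-GGXGG-NH₂ Cα/Cβ
values, shipped in code with provenance label `wishart1995`; any
`RandomCoilTable` with all 20 residue types can be substituted. Absolute Δδ
values shift by a few tenths of a ppm between published reference sets; the
segment classification operates on thresholds wide enough that the choice
does not move helix/coil calls. Neighbor corrections are off by default;
when enabled, only the pre-proline Cα correction (−2 ppm on the reference)
is applied — minimal, documented and testable.

Glycines (no Cβ) and residues missing an observed Cβ are reported as
`ca_only` with Δδ = δCα,obs − δCα,rc; they are excluded from windowed means
by default (configurable) because the CA-only value is on a different scale
from the two-carbon difference. Residues with no carbon data are `missing`.

### Segment classification

Per-residue smoothed values are a centered running mean over `window`
(default 5, odd) residues *with data*, shrinking at the edges. Classes:
stable helix if smoothed Δδ ≥ 2.0 ppm, transient helix in [0.5, 2.0), 
extended if ≤ −0.5, else coil (all thresholds configurable; the defaults
put the canonical "well-formed helix ≈ 3 ppm" value safely inside stable
and the "transient helix ≈ 1–2 ppm" band inside transient). Maximal runs of
one class become segments when they span ≥ `min_length` (default 4)
residues; shorter non-coil runs are absorbed into coil. A numbering gap of
≤ 1 data-less residue (prolines, unassigned) does not break a run — with
the default unassigned pattern no two consecutive residues are missing, so
a single-residue bridge is exactly what the data requires. Classification
is fully deterministic.

With propensity 0.5 planted on residues 342–385 and 0.15 ppm shift noise,
the 5-point running mean has a standard error of ≈ 0.07·3 ppm, so interior
residues sit 10σ inside the transient band; boundary blur from smoothing is
at most ~2 residues per side, which is why the recovery check allows ≤ 5
residues of over-call.

## Titration mapping

Intensity ratios are bound/free peak-height ratios per residue and
titration point; residues absent at a point are reported as not detected,
never as ratio 0. Peaks are matched by assignment label only — the inputs
are assigned lists, so positional nearest-neighbor matching would only add
failure modes.

CSPs use the standard weighted Euclidean combination
CSP = √(ΔδH² + (w·ΔδN)²) with w = 0.14 to compensate the wider ¹⁵N ppm
scale. The significance flag defaults to a 0.005 ppm reporting threshold —
an unusually low cutoff that we treat purely as a plotting/reporting
default, not an inference criterion; it is configurable.

The binding-segment caller is deliberately *relative*: at the default
calling point (the 10:1 spectrum) essentially every residue of an IDP bound
to a ribosome-sized partner is attenuated, so the baseline is the median
ratio across residues at that point and a residue is site-flagged when its
ratio ≤ `drop_factor` (default 0.5) × baseline. Flagged runs are merged
across numbering gaps ≤ `max_gap` (default 1) residues — covering
prolines, unassigned positions and an occasional noise-driven interior miss
— and reported when spanning ≥ `min_length` (default 3) residues. A
baseline needs ≥ 5 residues with data, else the call errors out.

## Ligand-depletion Kd fit

The isotherm is the exact two-component mass-action solution: with totals
[A] (titrant) and [B] (labelled protein), the complex concentration is the
smaller root of (A−x)(B−x) = Kd·x and FB = x/B. It is evaluated as
FB = 2A / (S + √(S² − 4AB)) with S = A+B+Kd, which is algebraically
identical to the quadratic formula but immune to catastrophic cancellation
when 4AB ≪ S² (A ≪ B or A ≫ B). The implementation is checked against an
independent bracketed-bisection solver on the mass-action balance to 1e-9
over six orders of magnitude of (A, B, Kd).

The dose–response model is response = offset + amplitude·FB(A; B, Kd), fit
by bounded nonlinear least squares (`scipy.optimize.least_squares`), with
Kd bounded below at 1e-6 nM to keep the model analytic. Amplitude is
always fitted (normalized MST responses rarely saturate exactly at 1);
offset fitting is off by default. Concentrations are held in nM
internally; Kd is reported in µM.

**Multi-start.** Under strong depletion (B ≫ Kd) the residual surface is
bimodal in Kd: besides the true minimum there is a shallow decoy at
Kd ≫ B where a large amplitude mimics the near-linear low-concentration
rise. A single start at the half-maximal concentration can roll into the
decoy, so the default fit starts from that heuristic plus a log-spaced Kd
grid spanning the titrant range and keeps the lowest-RSS solution. An
explicit `init_kd` disables the multi-start. A non-converged optimizer is
reported as `converged=False`, never silently.

**Identifiability.** At the study conditions (B = 20 µM, Kd = 0.45 µM,
B/Kd ≈ 44, 15 points, 1% multiplicative noise) Kd and amplitude are
strongly correlated and the estimator is intrinsically high-variance: the
information about Kd lives almost entirely in the curvature near A ≈ B.
The planted-recovery check therefore uses a ±20% tolerance, and the
parameter-recovery property is stated on the *median* error over seeds.

**Bootstrap.** Kd intervals come from a residual-resampling bootstrap
(percentile method, deterministic given a seed; > 20% replicate-refit
failures is an error). The default resamples *relative* residuals
(rᵢ/ŷᵢ) and reapplies them multiplicatively, matching the
signal-proportional error of normalized dose–response data; plain additive
resampling is available (`residual_type="absolute"`) but on this model it
underestimates the interval badly, because the fit leaves near-zero
residuals at the few high-signal, high-leverage points.

## CD ellipticity

Mean residue ellipticity: [θ]λ = θλ(mdeg) / (10 · c_molar · l_cm · N_res),
with c_molar derivable from mg/mL plus mean residue weight × N_res. θ222
and θ208 are read by linear interpolation (exact on grid points).
Classification cutoffs: coiled-coil when both bands are negative and
θ222/θ208 ≥ 0.95 (two-stranded coiled coils sit near 1.03); helical for
ratios in [0.6, 0.95); disordered when the global minimum lies at ≤ 203 nm
and |θ222| ≤ 0.25 of the deepest band; otherwise mixed. These are
heuristics on a continuous diagnostic, fully configurable, and the ratio is
invariant to units and scaling (so it is indifferent to whether spectra
were converted before computing it). Replicate concentrations are
summarized independently, never averaged.

## Synthetic data

One `SyntheticStudyConfig` holds all ground truth. Defaults: an 83-residue
chain numbered 320–402 whose landmark residues (W320, V321, R322, S323,
L325, I327, K328, V330, S341, P342, I348, F349, Q350, K353, N355, A359,
R365, Q370, E373, E378, S379, E382, Q385, S387, K388, I398, N399, K402)
are fixed and whose filler positions alternate Ala/Ser — explicitly *not*
the true protein sequence. Two filler prolines (335, 394) bring the chain
to 3 prolines / 80 non-proline amides, and 15 fixed amide-unassigned
positions (including S323, Q350, S379, N399, K402) give a 65/80 = 81%
assignment yield; the unassigned set is spread so that no two consecutive
residues are missing. Helix propensity is 0.5 on 342–385 (0.05 elsewhere);
the binding profile is 1.0 on 321–327 and 348–370; Kd 0.45 µM; titration
at 45 µM protein and ratios 400/100/10/5:1; MST at 20 µM labelled protein
over the 15-point, 1.21–20,000 nM two-fold series, amplitude 1, 1% noise.

Shift tables plant Δδ = 3.0·p: δCα = rc + 2.4p + ε, δCβ = rc − 0.6p + ε′,
ε ~ N(0, 0.15 ppm). The 2.4/0.6 split mirrors the larger Cα contribution
to the helix signature.

The titration intensity model is phenomenological. At each ratio the bound
fraction f comes from the depletion isotherm (reusing `binding_fit`), and
the expected ratio of residue i is ρᵢ = max(0, 1 − f·(k_global +
k_site·bᵢ)) with k_global = 5, k_site = 3. A population-weighted average
alone cannot produce an 80% on-site intensity loss at f ≈ 0.1; the linear
amplification stands in for exchange broadening against a slowly tumbling
70S complex and is calibrated so the 10:1 point shows the ~50% global /
~80% on-site contrast (f ≈ 0.0989 gives ρ ≈ 0.505 off-site, 0.209
on-site). Peaks with ρ ≤ 0 are dropped (broadened beyond detection), which
at 5:1 removes the site residues entirely — matching the qualitative
behaviour of a tight titration endpoint. Intensity noise is multiplicative
lognormal (sd 0.05); peak positions drift deterministically by
f·bᵢ·(0.02 ppm ¹H, 0.1 ppm ¹⁵N), the fast-exchange CSP signature, with no
positional noise.

CD spectra come from an analytic Gaussian band basis (helix: +193, −208,
−222 nm with equal-depth negative bands; coil: deep −200 nm band with a
weak positive tail), mixed linearly by helix fraction. This is a fixture
construction with the right diagnostic behaviour (helix_fraction 1 →
ratio ≈ 1; 0 → disordered), not a physical CD model.

All randomness flows through NumPy `default_rng` (PCG64) seeded as
`[seed, stream]` with one fixed stream id per generator, so every artifact
is bit-for-bit reproducible for a fixed seed across platforms, and
changing one generator's draws never perturbs another's.

**What passing tests do not show.** The generators emulate the statistical
shape of the analysis inputs, not the physics behind them: no lineshapes,
no relaxation, no chemical-exchange kinetics, no real CD basis spectra, no
baseline/phasing artifacts, and a fictional filler sequence. Planted
recovery demonstrates that the analysis is correct and well-calibrated on
data satisfying its own assumptions; it does not validate those
assumptions on real spectra.

## Pipeline and problem sizes

The pipeline runs stages in dependency order, writes per-stage TSV/JSON,
an effective-config YAML and a manifest (config hash, seed, versions,
timestamp); deterministic outputs re-run byte-identically. Plots are
optional artifacts and never inputs. All default analyses run on the
83-residue chain, 4 titration points and the 15-point MST curve — seconds
of compute — and the oracle cross-checks use 1000 random triples; these
sizes are the study's own and there is nothing to scale up.

## Known limitations

- The binding-segment caller assumes contiguous sites and a unimodal ratio
  distribution per point; interleaved single-residue sites below
  `min_length` are invisible by design.
- The CA-only (glycine) secondary shift is reported but not classified by
  default; chains rich in glycine need `include_ca_only=True` and a
  rescaled threshold set.
- Kd estimates in the deep-depletion regime carry large seed-to-seed
  scatter at 1% noise (see Identifiability); the bootstrap interval, not
  the point estimate, is the quantity to report.
- The NMR-STAR reader covers the assigned-chemical-shift loop dialect this
  package writes (and the equivalent BMRB loop subset), not general STAR.
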