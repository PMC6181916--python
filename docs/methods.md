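# Methods

## Dual-reporter noise decomposition

Two identical promoters driving distinguishable fluorophores in the same
cell give, per cell i and reporter j, an output x_ij. Normalising each
channel by its sample mean, the statistics are

- η²_tot — mean of the two per-channel population variances of the
  normalised outputs. The classic definition is written for a single
  channel; how two channels should be combined is a genuine choice, and we
  use the symmetric mean (both per-channel values are also reported, and
  the combined value reduces to either one when they agree).
- η²_int = ½ Var(a/⟨a⟩ − b/⟨b⟩) — the difference cancels everything shared
  by the reporters, leaving twice the uncorrelated variance.
- η²_ext = η²_tot − η²_int, an exact identity by construction. On finite
  samples it can be negative; we report the value unclipped and set a flag
  rather than hide the sampling fluctuation.
- ρ — Pearson correlation of the two raw channels. Pearson correlation is
  invariant to per-channel affine maps, so raw vs. normalised only matters
  if a background offset remains; we compute it on background-corrected
  outputs.

Variances are population variances (divide by n) by default, matching the
STD² notation of the field; `ddof=1` is available. Normalising means are
per replicate, never pooled across replicates.

Uncertainty: cell-level bootstrap (resample cells with replacement,
SD over resamples) for single replicates, and mean ± SEM across
biological replicates when ≥ 2 are available.

## Generative models (synthgen)

The default family is **additive Gaussian**: x_ij = μ(1 + e_i + ι_ij) with
e_i ~ N(0, η²_ext) shared across reporters and ι_ij ~ N(0, η²_int)
independent. Under this family the estimators above are exactly unbiased,
which makes parameter-recovery tests sharp; the reporters are jointly
bivariate normal with per-channel CV √(η²_int+η²_ext) and correlation
η²_ext/(η²_int+η²_ext). Negative outputs are retained — truncation at zero
would bias every moment at the CV (~0.5) typical of an induced stress
reporter. A **multiplicative lognormal** family (mean-1 factors with the
stated squared CVs) is provided for realism; under it the difference-based
intrinsic estimator converges to η²_int(1+η²_ext), a bias the test suite
asserts analytically rather than pretending it away.

The paper-style analysis does not fix a distributional family; both
families here are assumptions, and conclusions that depend on tails
(e.g. responder fractions) should be read accordingly.

**Field images** place non-overlapping ellipses (axis ratio 0.7–1.0,
random orientation) with uniform interior intensity = true total / pixel
area, over a uniform background, with optional Gaussian read noise,
Poisson shot noise and Gaussian blur (all off by default except where a
test states otherwise). Uniform interiors keep ground-truth totals exact;
no point-spread function is modelled, so segmentation difficulty is milder
than in real micrographs — passing tests validate the quantification
arithmetic, not robustness to real optics. Integrated brightness defaults
to 3×10⁵ counts/cell (`ImageParams.mean_total`), typical of a
well-exposed induced reporter; table simulations keep their own
`mean_output` (default 1000 a.u.) so the two fixtures are independent.
Placement uses bounded rejection sampling (200 tries per cell) and raises
a placement error on overcrowded fields.

**Phospho timecourses** follow a double-exponential peak-and-decline
curve: exponential rise from the basal fraction reaching the peak exactly
at `peak_time` (rise constant `peak_time/3`), then exponential relaxation
to a plateau with constant `decay_time`. Defaults (base 0.05, peak 0.35,
peak at 5 min, decay 8 min, plateau 0.08, timepoints 0–30 min) emulate a
transient phosphorylation peak around 5 minutes reaching under 40% of the
pool — a weak stimulus, in contrast to a hyperosmotic shock that
phosphorylates essentially everything. Band intensities carry independent
multiplicative lognormal noise; at zero noise the band ratio reproduces
the curve exactly.

**Glycerol assays** invert the forward conversion (linear in
concentration), so the zero-noise round trip is exact to machine
precision.

## Per-cell image quantification (imgquant)

Output = Σ(pixels in cell) − background × area, where background is the
**mode** of the intensity histogram of all pixels not assigned to any
cell. The mode estimator is deliberately pinned down: fixed-width bins of
max(1 a.u., Freedman–Diaconis width), mode = centre of the most populated
bin, ties broken toward lower intensity; it requires ≥ 1000 background
pixels (configurable) and errors otherwise. Adding a constant to every
pixel shifts the mode by that constant and leaves corrected outputs
(nearly) unchanged — exactly unchanged up to bin-placement quantisation,
which is why the invariance test uses a small tolerance.

Segmentation is a simple global-threshold segmenter (Otsu by default,
explicit threshold accepted) with connected components and a minimum-area
filter. It stands in for dedicated bright-field segmentation tools and is
validated only on synthetic fluorescence fields; cells touching the field
border are flagged and excluded by default, and merged cells surface
through the area QC flag. Coordinates are 0-based row-major; 0 labels
background.

Accuracy regime: with read noise σ=5 and ≥1000 background pixels the
dominant error is the mode's bin quantisation (≤ ~0.5 a.u.), which scales
with cell area; for the default brightness this is ≪ 1% per cell, but
relative error necessarily blows up for cells whose true total approaches
zero — the ≥ 99%-within-2% guarantee is about the population, not every
conceivable dim cell.

## Blot and timecourse metrics (dynamics)

Band background correction subtracts the median intensity of a border
around the band shape; negative corrected intensities are clipped to zero
with a warning (a band cannot have negative protein). Phos-tag gels
resolve phosphorylated and unphosphorylated forms of the same protein, so
fraction = phospho/(phospho+unphospho) is absolute; conventional gels give
phospho/total in arbitrary, within-blot units. AUC uses the trapezoid rule
on the observed timepoints — no integration rule is canonical for sparse
blot timecourses, and trapezoid is exact for the piecewise-linear reading
of the data; relative AUC = 100 × strain/reference. AUC can be computed on
either the fraction series or the normalised-abundance series; both are
supported because published panels use both. Fold changes divide group
means by the same group's t₀ mean (not per-cell ratios, which are unstable
near zero). Responder fraction uses output > mean + k·SD of an
unstimulated reference (k = 3 by default — our rule, stated because rare
responder fractions depend on it) with a Wilson binomial CI.

## Glycerol conversions

Extracellular production per cell, tracked dimensionally:

    conc [ng/µL] × 10³ [µL/mL] → ng per mL supernatant
    ÷ (OD × 3×10⁷ cells/mL at OD 1) → ng/cell
    × Vrel (cell volume relative to t₀)
    × 10³/92.09 [pmol/ng] → pmol/cell

A widely printed form of this transformation carries a "10⁶ µL/mL" factor
and no mass→mole step; both are dimensionally inconsistent (1 mL = 10³ µL,
and pmol requires the molar mass), so this package implements the coherent
chain above, fixed by the unit-tracking oracle in the test suite
(9.209 ng/µL at OD 1, Vrel 1 → exactly 10⁵ pmol over 3×10⁷ cells =
3.333×10⁻³ pmol/cell).

Intracellular concentration divides the OD-normalised per-cell amount by
the molar mass and a 40 fL cell volume, using 2×10⁷ cells/OD. The two
assays use different printed cell-density constants (3×10⁷ /mL/OD vs.
2×10⁷ /OD); both live in `ConversionConstants`, overridable, never
hard-coded at call sites. All conversions are homogeneous of degree 1 in
concentration.

## Pipeline

One YAML config drives all stages; every random draw derives from the
config seed (replicate r uses seed + r; stage-specific offsets keep
streams independent). The manifest records the config, its SHA-256, seeds
and package versions. Logging goes to stderr; data only to declared paths.

## Problem sizes and numerical choices

Simulation-based tests use 2×10³–10⁵ cells and 3–8 replicates; Monte-Carlo
tolerances are 3 SD/SEM of the estimator measured from independent
replicates, never hand-picked constants. Ties, degenerate inputs and error
cases (zero-variance populations, empty masks, all-foreground thresholds,
non-positive means/OD/Vrel, unordered timepoints) raise typed errors or
produce exact zeros as documented per function.

## Known limitations

- No bright-field segmentation, cell tracking, flat-field correction or
  autofluorescence modelling; the image model omits the PSF.
- No mechanistic (telegraph/gamma) noise model inference — the
  decomposition is moment-based.
- Densitometry starts from band intensities; gel scans are out of scope.
- ANOVA/Tukey-style significance testing is delegated to standard
  statistical packages and not re-implemented here.
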