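# hogpipe

Quantitative single-cell analysis for dual-reporter MAPK pathway studies in
budding yeast. The package targets experiments in which a transcriptional
reporter of the High Osmolarity Glycerol (HOG) pathway is imaged in single
cells — for example after a heat shock in sorbitol-adapted cultures — and the
questions are *how much* each cell responded, *how variable* the response is,
and *where* that variability comes from.

It provides, as importable modules plus a thin `hogpipe` CLI:

- **`synthgen`** — synthetic fixtures with known ground truth: dual-reporter
  cell tables, multi-channel fluorescence fields of ellipse-shaped cells,
  phospho-fraction blot timecourses and glycerol assay tables.
- **`imgquant`** — per-cell transcriptional output from images and label
  masks: output = integrated fluorescence − (background mode × cell area).
- **`noise`** — intrinsic/extrinsic decomposition of dual-reporter
  variability with bootstrap and replicate uncertainty.
- **`dynamics`** — timecourse summaries (mean ± SEM, fold change vs. t₀),
  phos-tag fraction phosphorylated, blot background correction, trapezoidal
  AUC and relative AUC, responder fractions.
- **`glycerol`** — supernatant ng/µL → pmol glycerol per cell, OD-normalised
  amounts → intracellular molarity, and percent-of-t₀ timecourses.
- **`pipeline`** — YAML-config-driven orchestration of all stages with a
  reproducibility manifest.

## The statistic at the core

Two identical promoters driving distinguishable fluorophores (YFP and
tdTomato) in the same cell split cell-to-cell variability into a component
uncorrelated between the reporters (intrinsic, gene-expression noise) and a
correlated, cell-wide component (extrinsic). With x the background-corrected
output of a reporter and ⟨x⟩ its population mean:

    η²_tot = Var(x/⟨x⟩)                          (per channel, averaged)
    η²_int = ½ · Var(y/⟨y⟩ − t/⟨t⟩)
    η²_ext = η²_tot − η²_int
    ρ      = Pearson correlation of the two reporters

Under a purely additive model E[ρ] = η²_ext/η²_tot, so the correlation
itself reports the extrinsic share.

## Worked example

`python examples/noise_decomposition.py` simulates three replicate
populations (2000 cells each) with generative components η²_int = 0.12 and
η²_ext = 0.15 and decomposes them:

```
replicate 0: eta2_tot=0.270  eta2_int=0.119 (+/- 0.004)  eta2_ext=0.151  rho=0.560
replicate 1: eta2_tot=0.271  eta2_int=0.120 (+/- 0.004)  eta2_ext=0.151  rho=0.557
replicate 2: eta2_tot=0.262  eta2_int=0.117 (+/- 0.004)  eta2_ext=0.145  rho=0.555

across replicates (mean +/- SEM):
statistic     mean      sem  n_replicates
 eta2_tot 0.267717 0.002930             3
 eta2_int 0.118569 0.001078             3
 eta2_ext 0.149148 0.001901             3
      rho 0.557098 0.001355             3
       cv 0.517397 0.002838             3
```

The estimators recover the generative components; the between-reporter
correlation ρ ≈ 0.56 means ~56% of the variability is extrinsic
(cell-wide), while η²_int/η²_tot ≈ 44% is uncorrelated gene-expression
noise. The per-reporter coefficient of variation is ≈ 0.52.

Other capabilities, one script each, are under `examples/`:
`image_quantification.py` (segment + quantify a synthetic field),
`blot_metrics.py` (fraction phosphorylated and AUC ratios),
`glycerol_conversion.py` (unit conversions), `full_pipeline.py`
(config-driven run, equivalent to `hogpipe run-all --seed 1`).

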