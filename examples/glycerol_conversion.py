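"""Glycerol assay conversions: per-cell production and intracellular drop.

Converts supernatant glycerol concentrations (ng/uL) to pmol produced per
cell, and an OD-normalised intracellular series to molar concentration
expressed as percent of its pre-shift value.
"""

from hogpipe import glycerol, synthgen

# supernatant assay: three timepoints with growing OD and swelling cells
table = synthgen.simulate_glycerol_assay(
    true_pmol_per_cell=0.004,
    od=[0.40, 0.55, 0.72],
    vrel=[1.00, 1.08, 1.15],
    noise_cv=0.05,
    seed=4,
)
out = glycerol.convert_table(table)
print(out[["sample", "concentration_ng_per_ul", "od600", "vrel", "pmol_per_cell"]]
      .round(4).to_string(index=False))
print("true value: 0.0040 pmol/cell; each row applies the ng/uL -> pmol/cell unit chain.\n")

# intracellular timecourse after a 37 degC shift (ng glycerol per mL culture)
amounts = [110.0, 95.0, 80.0, 70.0]
ods = [0.50, 0.52, 0.55, 0.60]
conc = [glycerol.intracellular_concentration(a, o) for a, o in zip(amounts, ods)]
drop = glycerol.timecourse_drop(conc, times=[0, 10, 20, 60])
print(drop.round(4).to_string(index=False))
print("intracellular molarity falls to "
      f"{drop['percent_of_t0'].iloc[-1]:.0f}% of the pre-shift content.")
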