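"""Dual-reporter noise decomposition on a simulated induced population.

Simulates three replicate populations of cells carrying two identical
promoters driving different fluorophores, decomposes cell-to-cell
variability into intrinsic (uncorrelated) and extrinsic (correlated)
components, and summarises across replicates.
"""

from hogpipe import SimulationConfig, noise, synthgen

config = SimulationConfig(
    n_cells=2000,
    n_replicates=3,
    seed=1,
    mean_output=1000.0,   # a.u. integrated reporter fluorescence
    eta2_int_true=0.12,   # uncorrelated variance component
    eta2_ext_true=0.15,   # correlated, cell-wide variance component
)

decompositions = []
for rep in range(config.n_replicates):
    table, _ = synthgen.simulate_dual_reporter(config, replicate=rep)
    d = noise.decompose(table, "yfp", "tdtomato")
    d.sem = noise.bootstrap_uncertainty(table, n_boot=200, seed=config.seed + rep)
    decompositions.append(d)
    print(
        f"replicate {rep}: eta2_tot={d.eta2_tot:.3f}  eta2_int={d.eta2_int:.3f} "
        f"(+/- {d.sem['eta2_int']:.3f})  eta2_ext={d.eta2_ext:.3f}  rho={d.rho:.3f}"
    )

print("\nacross replicates (mean +/- SEM):")
print(noise.replicate_summary(decompositions).to_string(index=False))
print(
    "\nrho is the between-reporter correlation; the intrinsic share "
    f"eta2_int/eta2_tot = {decompositions[0].eta2_int / decompositions[0].eta2_tot:.0%} "
    "of variability is uncorrelated gene-expression noise."
)
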