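"""Run every pipeline stage from a config dict (same as `hogpipe run-all`).

Writes cell tables, a quantified synthetic field, noise decompositions,
a phospho timecourse and a glycerol table plus a reproducibility manifest
into ./hogpipe_demo_run/.
"""

import json

from hogpipe import pipeline

config = pipeline.default_config()
config["seed"] = 1
config["outdir"] = "hogpipe_demo_run"
config["simulation"]["n_cells"] = 1000

report = pipeline.run(config)
print(json.dumps(report["stages"], indent=1))
print("\noutputs:", *report["outputs"], sep="\n  ")
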