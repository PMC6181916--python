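"""Config-driven orchestration: simulate -> quantify -> decompose -> report.

A run is described by a single YAML file (see :func:`default_config` for
the schema) and executed stage by stage.  All randomness is seeded from
the config; a manifest with the config hash, seeds and package versions
is written next to the outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, dynamics, glycerol, imgquant, noise, synthgen

__all__ = ["default_config", "validate_config", "load_config", "run"]

log = logging.getLogger("hogpipe")

STAGES = ("simulate", "quantify", "noise", "dynamics", "glycerol")


def default_config() -> dict:
    return {
        "seed": 0,
        "outdir": "hogpipe_run",
        "stages": list(STAGES),
        "simulation": {
            "n_cells": 2000,
            "n_replicates": 3,
            "mean_output": 1000.0,
            "eta2_int_true": 0.12,
            "eta2_ext_true": 0.15,
            "noise_family": "additive-gaussian",
            "image": {
                "shape": [512, 512],
                "radius_range": [8.0, 14.0],
                "background": 100.0,
                "read_noise_sd": 2.0,
                "n_cells": 20,
            },
        },
        "quantification": {"min_area": 30, "min_background_pixels": 1000},
        "noise": {"channel_a": "yfp", "channel_b": "tdtomato", "n_boot": 200},
        "dynamics": {
            "base": 0.05,
            "peak": 0.35,
            "peak_time": 5.0,
            "decay_time": 8.0,
            "plateau": 0.08,
            "timepoints": [0, 2.5, 5, 10, 15, 20, 30],
            "noise_cv": 0.1,
        },
        "glycerol": {
            "true_pmol_per_cell": 0.004,
            "od": [0.4, 0.5, 0.6],
            "vrel": [1.0, 1.1, 1.2],
            "noise_cv": 0.05,
        },
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Return a list of violations; empty means the config is valid."""
    problems: list[str] = []
    if "seed" not in cfg:
        problems.append("missing required key: seed")
    elif not isinstance(cfg["seed"], int):
        problems.append("seed must be an integer")
    stages = cfg.get("stages", list(STAGES))
    for s in stages:
        if s not in STAGES:
            problems.append(f"unknown stage: {s!r}")
    sim = cfg.get("simulation", {})
    for key in ("eta2_int_true", "eta2_ext_true"):
        v = sim.get(key)
        if v is not None and (not np.isfinite(v) or v < 0):
            problems.append(f"simulation.{key} must be finite and >= 0")
    if sim.get("mean_output", 1) <= 0:
        problems.append("simulation.mean_output must be > 0")
    if sim.get("n_cells", 2) < 2:
        problems.append("simulation.n_cells must be >= 2")
    dyn = cfg.get("dynamics", {})
    for key in ("base", "peak", "plateau"):
        v = dyn.get(key)
        if v is not None and not (0 <= v <= 1):
            problems.append(f"dynamics.{key} must lie in [0, 1]")
    gly = cfg.get("glycerol", {})
    if any(o <= 0 for o in gly.get("od", [1])):
        problems.append("glycerol.od values must be positive")
    return problems


def _sim_config(cfg: dict, with_images: bool = False) -> synthgen.SimulationConfig:
    sim = {**default_config()["simulation"], **cfg.get("simulation", {})}
    img = sim.pop("image", None)
    image_params = None
    if with_images and img is not None:
        img = {**default_config()["simulation"]["image"], **img}
        image_params = synthgen.ImageParams(
            shape=tuple(img["shape"]),
            radius_range=tuple(img["radius_range"]),
            background=img["background"],
            read_noise_sd=img.get("read_noise_sd", 0.0),
            n_cells=img["n_cells"],
        )
    return synthgen.SimulationConfig(
        n_cells=sim["n_cells"],
        n_replicates=sim["n_replicates"],
        seed=cfg.get("seed", 0),
        mean_output=sim["mean_output"],
        eta2_int_true=sim["eta2_int_true"],
        eta2_ext_true=sim["eta2_ext_true"],
        noise_family=sim["noise_family"],
        image_params=image_params,
    )


def run(cfg: dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the run report (also written
    to ``<outdir>/report.json``)."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s: %(message)s")

    outdir = Path(outdir or cfg.get("outdir", "hogpipe_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", list(STAGES))
    report: dict = {"stages": {}, "outputs": []}

    def emit(name: str, obj) -> Path:
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        else:
            path.write_text(json.dumps(obj, indent=1, default=_json_default))
        report["outputs"].append(str(path))
        return path

    tables: list[pd.DataFrame] = []
    if "simulate" in stages:
        log.info("stage simulate")
        sim_cfg = _sim_config(cfg)
        for r in range(sim_cfg.n_replicates):
            table, truth = synthgen.simulate_dual_reporter(sim_cfg, replicate=r)
            tables.append(table)
            emit(f"cells_rep{r}.csv", table)
            synthgen.write_ground_truth(truth, outdir / f"truth_rep{r}")
            report["outputs"].append(str(outdir / f"truth_rep{r}.json"))
        report["stages"]["simulate"] = {"replicates": sim_cfg.n_replicates, "n_cells": sim_cfg.n_cells}

    if "quantify" in stages:
        log.info("stage quantify")
        q = {**default_config()["quantification"], **cfg.get("quantification", {})}
        img_cfg = _sim_config(cfg, with_images=True)
        images, truth = synthgen.simulate_field_image(img_cfg)
        for ch, arr in images.items():
            tifffile.imwrite(outdir / f"field_{ch}.tif", arr.astype(np.float32))
            report["outputs"].append(str(outdir / f"field_{ch}.tif"))
        field = imgquant.FieldImage(images)
        table = imgquant.quantify_field(
            field,
            truth.mask,
            min_area=q["min_area"],
            min_background_pixels=q["min_background_pixels"],
        )
        emit("quantified_cells.csv", table)
        err = {}
        for ch in images:
            rec = table.sort_values("cell")[ch].to_numpy()
            tru = truth.totals[ch][table.sort_values("cell")["cell"].to_numpy() - 1]
            err[ch] = float(np.median(np.abs(rec - tru) / tru))
        report["stages"]["quantify"] = {"n_cells": len(table), "median_rel_error": err}

    if "noise" in stages:
        log.info("stage noise")
        ncfg = {**default_config()["noise"], **cfg.get("noise", {})}
        if not tables:
            sim_cfg = _sim_config(cfg)
            tables = [
                synthgen.simulate_dual_reporter(sim_cfg, replicate=r)[0]
                for r in range(sim_cfg.n_replicates)
            ]
        decomps = [noise.decompose(t, ncfg["channel_a"], ncfg["channel_b"]) for t in tables]
        for r, d in enumerate(decomps):
            d.sem = noise.bootstrap_uncertainty(
                tables[r], ncfg["channel_a"], ncfg["channel_b"],
                n_boot=ncfg["n_boot"], seed=cfg.get("seed", 0) + 100 + r,
            )
        emit("noise_decomposition.json", [d.as_dict() for d in decomps])
        if len(decomps) >= 2:
            emit("noise_replicate_summary.csv", noise.replicate_summary(decomps))
        report["stages"]["noise"] = {
            "rho_mean": float(np.mean([d.rho for d in decomps])),
            "eta2_int_mean": float(np.mean([d.eta2_int for d in decomps])),
            "eta2_ext_mean": float(np.mean([d.eta2_ext for d in decomps])),
        }

    if "dynamics" in stages:
        log.info("stage dynamics")
        dcfg = {**default_config()["dynamics"], **cfg.get("dynamics", {})}
        lanes, truth = synthgen.simulate_phospho_timecourse(
            dcfg["base"], dcfg["peak"], dcfg["peak_time"], dcfg["decay_time"],
            dcfg["plateau"], dcfg["timepoints"], noise_cv=dcfg["noise_cv"],
            seed=cfg.get("seed", 0) + 200,
        )
        series = dynamics.blot_fraction_series(lanes)
        emit("phospho_timecourse.csv", series)
        report["stages"]["dynamics"] = {
            "auc": dynamics.auc(series["time"], series["fraction"]),
            "true_auc": truth.extra["auc"],
            "peak_fraction": float(series["fraction"].max()),
        }

    if "glycerol" in stages:
        log.info("stage glycerol")
        gcfg = {**default_config()["glycerol"], **cfg.get("glycerol", {})}
        table = synthgen.simulate_glycerol_assay(
            gcfg["true_pmol_per_cell"], gcfg["od"], gcfg["vrel"],
            noise_cv=gcfg["noise_cv"], seed=cfg.get("seed", 0) + 300,
        )
        converted = glycerol.convert_table(table)
        emit("glycerol.csv", converted)
        report["stages"]["glycerol"] = {
            "mean_pmol_per_cell": float(converted["pmol_per_cell"].mean()),
            "true_pmol_per_cell": gcfg["true_pmol_per_cell"],
        }

    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=_json_default).encode()
        ).hexdigest(),
        "seed": cfg.get("seed", 0),
        "hogpipe_version": __version__,
        "numpy_version": np.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=_json_default))
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
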