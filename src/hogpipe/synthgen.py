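"""Synthetic fixtures with known ground truth.

Generates the four kinds of data the downstream modules consume:

* dual-reporter per-cell tables with prescribed intrinsic (uncorrelated)
  and extrinsic (correlated) variance components,
* multi-channel fluorescence field images of ellipse-shaped cells over a
  noisy background, together with the true label mask,
* phospho-fraction immunoblot timecourses (peak-and-decline curves with
  multiplicative band noise),
* glycerol assay tables consistent with the per-cell conversion equations.

Every generator is deterministic given its seed; replicate r of a config
with seed s uses seed s + r.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .glycerol import ConversionConstants, extracellular_per_cell

__all__ = [
    "SimulationConfig",
    "ImageParams",
    "GroundTruth",
    "simulate_dual_reporter",
    "simulate_field_image",
    "simulate_phospho_timecourse",
    "simulate_glycerol_assay",
    "phospho_fraction_curve",
    "phospho_curve_auc",
    "write_ground_truth",
]


@dataclass(frozen=True)
class ImageParams:
    """Geometry and noise parameters for synthetic fluorescence fields.

    ``mean_total`` is the mean integrated fluorescence per cell in camera
    counts; the default (3e5 a.u.) puts interior pixels well above the
    background, as in a typical exposure of an induced reporter.
    """

    shape: tuple[int, int] = (512, 512)
    mean_total: float = 3e5
    radius_range: tuple[float, float] = (8.0, 14.0)
    background: float = 100.0
    read_noise_sd: float = 0.0
    shot_noise: bool = False
    min_separation: float = 4.0
    n_cells: int = 20
    blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("cell radii must be positive and ordered")
        if self.background < 0:
            raise ValueError("background level must be >= 0")
        if 2 * hi >= min(self.shape):
            raise ValueError("cells must fit within the field")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for dual-reporter populations.

    ``eta2_int_true`` and ``eta2_ext_true`` are the squared coefficients of
    variation of the uncorrelated (per-reporter) and correlated (cell-wide)
    components of expression, on the normalised-output scale.
    """

    n_cells: int = 2000
    n_replicates: int = 1
    seed: int = 0
    mean_output: float = 1000.0
    eta2_int_true: float = 0.12
    eta2_ext_true: float = 0.15
    noise_family: str = "additive-gaussian"
    image_params: ImageParams | None = None

    def __post_init__(self) -> None:
        for name in ("eta2_int_true", "eta2_ext_true"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.mean_output <= 0:
            raise ValueError("mean_output must be > 0")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.noise_family not in ("additive-gaussian", "multiplicative-lognormal"):
            raise ValueError(f"unknown noise_family: {self.noise_family!r}")


@dataclass
class GroundTruth:
    """True per-cell quantities behind a synthetic dataset."""

    totals: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None
    extrinsic_factor: np.ndarray | None = None
    intrinsic_deviates: dict[str, np.ndarray] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _mean_one_lognormal(rng: np.random.Generator, cv2: float, size) -> np.ndarray:
    """Lognormal deviates with mean exactly 1 and squared CV ``cv2``."""
    if cv2 == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_dual_reporter(
    config: SimulationConfig,
    channels: tuple[str, str] = ("yfp", "tdtomato"),
    replicate: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one replicate of a two-reporter population.

    Additive model: ``x_ij = mu * (1 + e_i + i_ij)`` with the cell-wide
    factor ``e_i ~ N(0, eta2_ext)`` shared by both reporters and
    ``i_ij ~ N(0, eta2_int)`` independent per reporter.  Negative outputs
    are retained: background-corrected fluorescence may be negative.

    Multiplicative model: ``x_ij = mu * E_i * I_ij`` with mean-1 lognormal
    factors of the stated squared CVs.  Under this family the
    difference-based intrinsic estimator converges to
    ``eta2_int * (1 + eta2_ext)`` rather than ``eta2_int`` (documented
    bias; exercised in the test suite).

    Returns a cell table with columns ``cell``, ``area`` and one output
    column per channel, plus the ground truth.
    """
    rng = np.random.default_rng(config.seed + replicate)
    n = config.n_cells
    mu = config.mean_output
    ch_a, ch_b = channels

    if config.noise_family == "additive-gaussian":
        e = rng.normal(0.0, np.sqrt(config.eta2_ext_true), size=n)
        ia = rng.normal(0.0, np.sqrt(config.eta2_int_true), size=n)
        ib = rng.normal(0.0, np.sqrt(config.eta2_int_true), size=n)
        xa = mu * (1.0 + e + ia)
        xb = mu * (1.0 + e + ib)
        extrinsic = 1.0 + e
    else:
        extrinsic = _mean_one_lognormal(rng, config.eta2_ext_true, n)
        ia = _mean_one_lognormal(rng, config.eta2_int_true, n)
        ib = _mean_one_lognormal(rng, config.eta2_int_true, n)
        xa = mu * extrinsic * ia
        xb = mu * extrinsic * ib

    table = pd.DataFrame(
        {
            "cell": np.arange(1, n + 1),
            "replicate": replicate,
            "area": np.full(n, np.nan),
            ch_a: xa,
            ch_b: xb,
        }
    )
    truth = GroundTruth(
        totals={ch_a: xa.copy(), ch_b: xb.copy()},
        extrinsic_factor=extrinsic,
        intrinsic_deviates={ch_a: ia, ch_b: ib},
        extra={"mean_output": mu, "noise_family": config.noise_family},
    )
    return table, truth


def _place_centers(
    rng: np.random.Generator, params: ImageParams, radii: np.ndarray
) -> np.ndarray:
    """Rejection-sample non-overlapping ellipse centres; bounded retries."""
    h, w = params.shape
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    max_tries = 200 * max(params.n_cells, 1)
    tries = 0
    for r in radii:
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place {params.n_cells} cells without overlap "
                    f"in a {h}x{w} field"
                )
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            ok = all(
                np.hypot(cy - py, cx - px) >= r + pr + params.min_separation
                for (py, px), pr in zip(centers, placed_r)
            )
            if ok:
                centers.append((cy, cx))
                placed_r.append(r)
                break
    return np.asarray(centers).reshape(-1, 2)


def simulate_field_image(
    config: SimulationConfig,
    channels: tuple[str, ...] = ("yfp", "tdtomato"),
    replicate: int = 0,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render a multi-channel field of ellipse cells plus its label mask.

    Each cell's interior pixels carry ``true total / pixel area`` so that,
    with noise disabled, the integrated signal over the true mask minus
    background x area reproduces the true total exactly.
    """
    if config.image_params is None:
        raise ValueError("image_params must be set to simulate field images")
    params = config.image_params
    rng = np.random.default_rng(config.seed + replicate)

    n = params.n_cells
    mask = np.zeros(params.shape, dtype=np.int32)
    images = {ch: np.full(params.shape, params.background, dtype=np.float64) for ch in channels}
    truth = GroundTruth(mask=mask)

    if n > 0:
        lo, hi = params.radius_range
        rmaj = rng.uniform(lo, hi, size=n)
        # minor axis within [0.7, 1.0] of major: mildly eccentric yeast-like shapes
        rmin = rmaj * rng.uniform(0.7, 1.0, size=n)
        theta = rng.uniform(0, np.pi, size=n)
        centers = _place_centers(rng, params, rmaj)

        # per-cell true totals: reuse the dual-reporter generative model
        cell_cfg = SimulationConfig(
            n_cells=max(n, 2),
            seed=config.seed + 7919,  # decoupled stream for expression values
            mean_output=params.mean_total,
            eta2_int_true=config.eta2_int_true,
            eta2_ext_true=config.eta2_ext_true,
            noise_family=config.noise_family,
        )
        expr_table, expr_truth = simulate_dual_reporter(
            cell_cfg, channels=("_a", "_b"), replicate=replicate
        )
        totals_by_channel: dict[str, np.ndarray] = {}
        for k, ch in enumerate(channels):
            col = "_a" if k % 2 == 0 else "_b"
            totals_by_channel[ch] = np.abs(expr_table[col].to_numpy()[:n])

        yy, xx = np.mgrid[0 : params.shape[0], 0 : params.shape[1]]
        for i in range(n):
            cy, cx = centers[i]
            ct, st = np.cos(theta[i]), np.sin(theta[i])
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            inside = (u / rmaj[i]) ** 2 + (v / rmin[i]) ** 2 <= 1.0
            mask[inside] = i + 1
            area = int(inside.sum())
            for ch in channels:
                images[ch][inside] += totals_by_channel[ch][i] / area

        truth.totals = {ch: totals_by_channel[ch] for ch in channels}
        truth.extra["centers"] = centers
        truth.extra["radii_major"] = rmaj
        truth.extra["radii_minor"] = rmin

    if params.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        for ch in channels:
            images[ch] = gaussian_filter(images[ch], params.blur_sigma)
    for ch in channels:
        if params.shot_noise:
            images[ch] = rng.poisson(np.clip(images[ch], 0, None)).astype(np.float64)
        if params.read_noise_sd > 0:
            images[ch] = images[ch] + rng.normal(0, params.read_noise_sd, params.shape)

    truth.mask = mask
    truth.extra["background"] = params.background
    return images, truth


def phospho_fraction_curve(
    t: np.ndarray,
    base: float,
    peak: float,
    peak_time: float,
    decay_time: float,
    plateau: float,
) -> np.ndarray:
    """Peak-and-decline phospho-fraction curve.

    Exponential rise from ``base`` reaching ``peak`` exactly at
    ``peak_time`` (rise constant ``peak_time / 3``), then exponential
    relaxation towards ``plateau`` with time constant ``decay_time``.
    Degenerates to a constant when base == peak == plateau and to a pure
    decay when ``peak_time == 0``.
    """
    t = np.asarray(t, dtype=float)
    f = np.empty_like(t)
    if peak_time > 0:
        tau_r = peak_time / 3.0
        norm = 1.0 - np.exp(-peak_time / tau_r)
        rising = t <= peak_time
        f[rising] = base + (peak - base) * (1.0 - np.exp(-t[rising] / tau_r)) / norm
    else:
        rising = t < 0
    late = ~rising
    f[late] = plateau + (peak - plateau) * np.exp(-(t[late] - peak_time) / decay_time)
    return f


def phospho_curve_auc(
    base: float,
    peak: float,
    peak_time: float,
    decay_time: float,
    plateau: float,
    t_end: float,
) -> float:
    """Closed-form integral of :func:`phospho_fraction_curve` on [0, t_end]."""
    auc = 0.0
    if peak_time > 0:
        tau_r = peak_time / 3.0
        norm = 1.0 - np.exp(-peak_time / tau_r)
        tp = min(peak_time, t_end)
        # integral of base + (peak-base)*(1-exp(-t/tau_r))/norm on [0, tp]
        auc += base * tp + (peak - base) / norm * (tp - tau_r * (1 - np.exp(-tp / tau_r)))
    if t_end > peak_time:
        dt = t_end - peak_time
        auc += plateau * dt + (peak - plateau) * decay_time * (1 - np.exp(-dt / decay_time))
    return auc


def simulate_phospho_timecourse(
    base: float,
    peak: float,
    peak_time: float,
    decay_time: float,
    plateau: float,
    timepoints: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    total_intensity: float = 1000.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample a phos-tag blot timecourse from the peak-and-decline model.

    Returns a lane table with columns ``time``, ``phospho``, ``unphospho``
    whose noise-free band ratio equals the generative fraction curve, and
    ground truth carrying the true curve and its analytic AUC.  Band noise
    is multiplicative lognormal with CV ``noise_cv``, independent per band.
    """
    for name, v in (("base", base), ("peak", peak), ("plateau", plateau)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} fraction must lie in [0, 1], got {v}")
    t = np.asarray(list(timepoints), dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")

    rng = np.random.default_rng(seed)
    frac = phospho_fraction_curve(t, base, peak, peak_time, decay_time, plateau)
    phospho = total_intensity * frac
    unphospho = total_intensity * (1.0 - frac)
    if noise_cv > 0:
        phospho = phospho * _mean_one_lognormal(rng, noise_cv**2, t.size)
        unphospho = unphospho * _mean_one_lognormal(rng, noise_cv**2, t.size)

    table = pd.DataFrame(
        {"lane": np.arange(1, t.size + 1), "time": t, "phospho": phospho, "unphospho": unphospho}
    )
    truth = GroundTruth(
        extra={
            "fraction": frac,
            "auc": phospho_curve_auc(base, peak, peak_time, decay_time, plateau, float(t[-1]))
            if t.size
            else 0.0,
            "params": dict(
                base=base, peak=peak, peak_time=peak_time, decay_time=decay_time, plateau=plateau
            ),
        }
    )
    return table, truth


def simulate_glycerol_assay(
    true_pmol_per_cell: float | Sequence[float],
    od: Sequence[float],
    vrel: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    constants: ConversionConstants | None = None,
) -> pd.DataFrame:
    """Emit supernatant glycerol concentrations consistent with the
    per-cell conversion, so that the forward conversion recovers the truth.

    ``true_pmol_per_cell`` may be scalar (same truth for all samples) or a
    per-sample sequence.  Multiplicative lognormal noise with CV
    ``noise_cv`` is applied to the emitted concentrations.
    """
    constants = constants or ConversionConstants()
    od = np.asarray(list(od), dtype=float)
    vrel = np.asarray(list(vrel), dtype=float)
    if np.any(od <= 0) or np.any(vrel <= 0):
        raise ValueError("OD and Vrel must be positive")
    truth = np.broadcast_to(np.asarray(true_pmol_per_cell, dtype=float), od.shape).copy()

    # invert the forward conversion (linear in concentration)
    unit = np.array(
        [extracellular_per_cell(1.0, o, v, constants) for o, v in zip(od, vrel)]
    )
    conc = truth / unit
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        conc = conc * _mean_one_lognormal(rng, noise_cv**2, conc.shape)
    return pd.DataFrame(
        {
            "sample": np.arange(1, od.size + 1),
            "concentration_ng_per_ul": conc,
            "od600": od,
            "vrel": vrel,
            "true_pmol_per_cell": truth,
        }
    )


def write_ground_truth(truth: GroundTruth, prefix: str | Path) -> None:
    """Persist ground truth as JSON (+ a label-mask TIFF when present)."""
    prefix = Path(prefix)
    payload = {}
    for k, v in asdict(truth).items():
        if k == "mask":
            continue
        payload[k] = _jsonify(v)
    prefix.with_suffix(".json").write_text(json.dumps(payload, indent=1))
    if truth.mask is not None:
        tifffile.imwrite(str(prefix) + "_mask.tif", truth.mask.astype(np.uint16))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
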