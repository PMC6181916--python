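"""Population timecourse and immunoblot metrics.

Covers the quantitative readouts of reporter-induction experiments:
per-timepoint population mean +/- SEM and fold change relative to t0,
phos-tag fraction of phosphorylated protein, blot band background
correction, trapezoidal AUC of a phospho timecourse and AUC expressed
relative to a reference strain, and the fraction of "responder" cells
above a reference-population threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "BlotLane",
    "band_background_correct",
    "fraction_phosphorylated",
    "normalized_phospho",
    "auc",
    "relative_auc",
    "blot_fraction_series",
    "timecourse_summary",
    "responder_fraction",
]


@dataclass(frozen=True)
class BlotLane:
    """One gel lane: band intensities at one timepoint.

    For phos-tag gels ``phospho`` and ``unphospho`` are the shifted and
    unshifted bands of the same protein; for conventional gels use
    ``phospho`` and ``total`` (loading control).
    """

    lane: int
    time: float
    phospho: float
    unphospho: float | None = None
    total: float | None = None


def band_background_correct(intensity: float, border_median: float) -> float:
    """Subtract the local background (median of a border around the band).

    Negative corrected intensities are clipped to zero with a warning.
    """
    if not (np.isfinite(intensity) and np.isfinite(border_median)):
        raise ValueError("band intensity and border median must be finite")
    corrected = intensity - border_median
    if corrected < 0:
        warnings.warn(
            f"band intensity {intensity} below background {border_median}; clipping to 0",
            stacklevel=2,
        )
        return 0.0
    return float(corrected)


def fraction_phosphorylated(phospho: float, unphospho: float) -> float:
    """Fraction of protein in the phosphorylated (shifted) band.

    Phos-tag gels resolve both forms with a single antibody, so
    ``phospho / (phospho + unphospho)`` is an absolute fraction in [0, 1].
    """
    total = phospho + unphospho
    if total <= 0:
        raise ValueError("zero total band signal; fraction undefined")
    if phospho < 0 or unphospho < 0:
        raise ValueError("band intensities must be non-negative")
    return float(phospho / total)


def normalized_phospho(phospho: float, total: float) -> float:
    """Phospho signal normalised to total-protein loading (conventional gel).

    Arbitrary units; comparable across lanes of the same blot only.
    """
    if total <= 0:
        raise ValueError("zero total signal; normalisation undefined")
    return float(phospho / total)


def auc(times, values) -> float:
    """Trapezoidal area under a timecourse (a.u. x min)."""
    t = np.asarray(list(times), dtype=float)
    v = np.asarray(list(values), dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def relative_auc(times, values, ref_times, ref_values) -> float:
    """Strain AUC as a percentage of a reference strain's AUC."""
    ref = auc(ref_times, ref_values)
    if ref == 0:
        raise ValueError("reference AUC is zero")
    return 100.0 * auc(times, values) / ref


def blot_fraction_series(lanes: pd.DataFrame) -> pd.DataFrame:
    """Fraction phosphorylated per lane of a phos-tag blot table.

    Expects columns ``time``, ``phospho``, ``unphospho`` (background
    corrected); returns time-ordered fractions.
    """
    out = lanes.sort_values("time").reset_index(drop=True).copy()
    out["fraction"] = [
        fraction_phosphorylated(p, u) for p, u in zip(out["phospho"], out["unphospho"])
    ]
    return out


def timecourse_summary(
    cells: pd.DataFrame,
    value: str,
    time: str = "time",
    groups: list[str] | None = None,
    fold_change: bool = True,
) -> pd.DataFrame:
    """Per-timepoint population mean, SEM and fold change vs. t0.

    Cells are grouped by ``groups`` (e.g. strain, medium) and ``time``;
    fold change divides each group's mean by the same group's mean at its
    earliest timepoint.
    """
    keys = (groups or []) + [time]
    rows = []
    for key, sub in cells.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = sub[value].to_numpy(dtype=float)
        rows.append(
            dict(zip(keys, key))
            | {
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
                "n_cells": int(vals.size),
            }
        )
    out = pd.DataFrame(rows)
    if fold_change:
        gcols = groups or []
        if gcols:
            t0 = out.loc[out.groupby(gcols)[time].transform("min") == out[time]]
            t0 = t0.set_index(gcols)["mean"]
            base = out.set_index(gcols).index.map(t0)
            base = np.asarray(base, dtype=float)
        else:
            base = np.full(len(out), out.loc[out[time].idxmin(), "mean"])
        if np.any(base == 0):
            raise ValueError("t0 group mean is zero; fold change undefined")
        out["fold_change"] = out["mean"] / base
    return out


def responder_fraction(
    outputs,
    reference,
    k: float = 3.0,
    alpha: float = 0.05,
) -> dict:
    """Fraction of cells induced above an unstimulated reference population.

    A cell responds when its output exceeds ``mean(reference) +
    k * SD(reference)``.  Returns the fraction with a Wilson binomial
    confidence interval.
    """
    x = np.asarray(list(outputs), dtype=float)
    ref = np.asarray(list(reference), dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference population")
    if x.size == 0:
        raise ValueError("empty output population")
    threshold = ref.mean() + k * ref.std(ddof=1 if ref.size > 1 else 0)
    n_resp = int((x > threshold).sum())
    lo, hi = proportion_confint(n_resp, x.size, alpha=alpha, method="wilson")
    return {
        "fraction": n_resp / x.size,
        "n_responders": n_resp,
        "n_cells": int(x.size),
        "threshold": float(threshold),
        "ci_low": float(lo),
        "ci_high": float(hi),
    }
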