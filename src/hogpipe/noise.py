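"""Intrinsic/extrinsic decomposition of dual-reporter variability.

Two identical promoters driving distinguishable fluorophores in the same
cell separate cell-to-cell variability into an uncorrelated (intrinsic)
part and a correlated, cell-wide (extrinsic) part:

    eta2_tot = var(x / <x>)                       (per channel, averaged)
    eta2_int = 0.5 * var(a/<a> - b/<b>)
    eta2_ext = eta2_tot - eta2_int

with x the background-corrected output, <.> the sample mean, and
variances population (divide by n) by default.  eta2_ext is reported, not
clipped, when a finite sample drives it negative; a flag marks that case.
The Pearson correlation rho between the two raw channels is reported
alongside; under a purely additive model E[rho] -> eta2_ext / eta2_tot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "NoiseDecomposition",
    "decompose",
    "bootstrap_uncertainty",
    "replicate_summary",
]

_STATS = ("eta2_tot", "eta2_int", "eta2_ext", "rho", "cv")


@dataclass
class NoiseDecomposition:
    """Result of a dual-reporter noise decomposition.

    ``cv`` is the mean of the two per-channel coefficients of variation;
    the per-channel values are kept in ``cv_per_channel`` and
    ``eta2_tot_per_channel``.
    """

    eta2_tot: float
    eta2_int: float
    eta2_ext: float
    rho: float
    cv: float
    n_cells: int
    eta2_tot_per_channel: tuple[float, float]
    cv_per_channel: tuple[float, float]
    negative_ext: bool = False
    sem: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def _channels(cells: pd.DataFrame | np.ndarray, channel_a, channel_b):
    if isinstance(cells, pd.DataFrame):
        a = cells[channel_a].to_numpy(dtype=float)
        b = cells[channel_b].to_numpy(dtype=float)
    else:
        arr = np.asarray(cells, dtype=float)
        a, b = arr[:, 0], arr[:, 1]
    return a, b


def decompose(
    cells: pd.DataFrame | np.ndarray,
    channel_a: str = "yfp",
    channel_b: str = "tdtomato",
    ddof: int = 0,
) -> NoiseDecomposition:
    """Decompose cell-to-cell variability of a two-channel cell table.

    Parameters
    ----------
    cells
        Cell table with one row per cell, or an (n, 2) array.
    ddof
        0 (population variance, default) or 1 (unbiased).

    Raises
    ------
    ValueError
        Fewer than 2 cells, or a non-positive channel mean (the
        normalisation is undefined).
    """
    a, b = _channels(cells, channel_a, channel_b)
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 cells, got {n}")
    ma, mb = a.mean(), b.mean()
    if ma <= 0 or mb <= 0:
        raise ValueError("channel means must be positive to normalise")

    an, bn = a / ma, b / mb
    var_a = an.var(ddof=ddof)
    var_b = bn.var(ddof=ddof)
    eta2_tot = 0.5 * (var_a + var_b)
    eta2_int = 0.5 * (an - bn).var(ddof=ddof)
    eta2_ext = eta2_tot - eta2_int

    sa, sb = a.std(ddof=ddof), b.std(ddof=ddof)
    if sa > 0 and sb > 0:
        rho = float(np.corrcoef(a, b)[0, 1])
    else:
        rho = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
    cva, cvb = sa / ma, sb / mb

    return NoiseDecomposition(
        eta2_tot=float(eta2_tot),
        eta2_int=float(eta2_int),
        eta2_ext=float(eta2_ext),
        rho=float(np.clip(rho, -1.0, 1.0)),
        cv=float(0.5 * (cva + cvb)),
        n_cells=int(n),
        eta2_tot_per_channel=(float(var_a), float(var_b)),
        cv_per_channel=(float(cva), float(cvb)),
        negative_ext=bool(eta2_ext < 0),
    )


def bootstrap_uncertainty(
    cells: pd.DataFrame | np.ndarray,
    channel_a: str = "yfp",
    channel_b: str = "tdtomato",
    n_boot: int = 1000,
    seed: int = 0,
    ddof: int = 0,
) -> dict[str, float]:
    """SEM of each decomposition statistic by cell-level bootstrap.

    Resamples cells with replacement ``n_boot`` times and returns the SD
    of each statistic over resamples.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    a, b = _channels(cells, channel_a, channel_b)
    n = a.size
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {s: [] for s in _STATS}
    pairs = pd.DataFrame({"a": a, "b": b})
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        d = decompose(pairs.iloc[idx], "a", "b", ddof=ddof)
        for s in _STATS:
            draws[s].append(getattr(d, s))
    return {s: float(np.std(draws[s], ddof=1)) for s in _STATS}


def replicate_summary(replicates: list[NoiseDecomposition]) -> pd.DataFrame:
    """Mean and SEM of each statistic across independent replicates."""
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates for a mean +/- SEM summary")
    rows = []
    for s in _STATS:
        vals = np.array([getattr(r, s) for r in replicates], dtype=float)
        rows.append(
            {
                "statistic": s,
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                "n_replicates": int(vals.size),
            }
        )
    return pd.DataFrame(rows)
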