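"""Glycerol assay conversions.

Two independent conversions are supported, each with its own cell-density
constant:

* extracellular production per cell (pmol/cell) from supernatant glycerol
  concentration (ng/uL), culture OD600 and relative cell volume, using
  3e7 cells/mL at OD 1;
* intracellular concentration (mol/L) from an OD-normalised glycerol
  amount, using 2e7 cells per OD unit per mL and a 40 fL cell volume.

Unit chain for the per-cell conversion, tracked dimensionally::

    conc [ng/uL] * 1e3 [uL/mL]        -> ng/mL of supernatant
    / (OD * 3e7 [cells/mL at OD 1])   -> ng/cell
    * Vrel                            -> volume-corrected ng/cell
    * 1e3 / 92.09 [pmol/ng]           -> pmol/cell

The widely printed form of this transformation carries a "1e6 uL/mL"
factor and omits the mass-to-mole step; both are dimensionally
inconsistent (1 mL = 1e3 uL, and pmol requires dividing by the molar
mass), so this module implements the coherent chain above instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConversionConstants",
    "extracellular_per_cell",
    "intracellular_concentration",
    "timecourse_drop",
    "convert_table",
]

GLYCEROL_MOLAR_MASS = 92.09  # g/mol


@dataclass(frozen=True)
class ConversionConstants:
    """Overridable constants of the two conversions.

    cells_per_ml_per_od : cell density at OD600 = 1 (extracellular assay).
    cells_per_od        : cells per mL per OD unit (intracellular assay).
    cell_volume_fl      : single-cell volume in femtolitres.
    molar_mass          : glycerol molar mass, g/mol.
    """

    cells_per_ml_per_od: float = 3e7
    cells_per_od: float = 2e7
    cell_volume_fl: float = 40.0
    molar_mass: float = GLYCEROL_MOLAR_MASS

    def __post_init__(self) -> None:
        for name in ("cells_per_ml_per_od", "cells_per_od", "cell_volume_fl", "molar_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def extracellular_per_cell(
    concentration_ng_per_ul: float,
    od: float,
    vrel: float = 1.0,
    constants: ConversionConstants | None = None,
) -> float:
    """Glycerol produced per cell, in pmol/cell.

    Parameters
    ----------
    concentration_ng_per_ul
        Supernatant glycerol concentration (ng/uL). May be negative after
        blank subtraction; the conversion is linear and sign-preserving.
    od
        Culture OD600 at the sampled timepoint (> 0).
    vrel
        Cell volume relative to t0 (> 0, dimensionless).
    """
    constants = constants or ConversionConstants()
    if od <= 0 or vrel <= 0:
        raise ValueError("OD and Vrel must be positive")
    ng_per_ml = concentration_ng_per_ul * 1e3
    ng_per_cell = ng_per_ml / (od * constants.cells_per_ml_per_od)
    return ng_per_cell * vrel * 1e3 / constants.molar_mass


def intracellular_concentration(
    amount_ng_per_ml: float,
    od: float,
    constants: ConversionConstants | None = None,
) -> float:
    """Intracellular glycerol concentration, in mol/L.

    ``amount_ng_per_ml`` is the glycerol content of the boiled-cell extract
    per mL of culture; division by OD x cells/OD gives the per-cell amount,
    which the cell volume converts to a molar concentration.
    """
    constants = constants or ConversionConstants()
    if od <= 0:
        raise ValueError("OD must be positive")
    ng_per_cell = amount_ng_per_ml / (od * constants.cells_per_od)
    mol_per_cell = ng_per_cell * 1e-9 / constants.molar_mass
    litres_per_cell = constants.cell_volume_fl * 1e-15
    return mol_per_cell / litres_per_cell


def timecourse_drop(values, times=None) -> pd.DataFrame:
    """Express a concentration series as percent of its t0 value.

    The first element is taken as t0; it must be positive.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    if v[0] <= 0:
        raise ValueError("t0 value must be positive to normalise")
    t = np.arange(v.size) if times is None else np.asarray(list(times), dtype=float)
    return pd.DataFrame({"time": t, "value": v, "percent_of_t0": 100.0 * v / v[0]})


def convert_table(
    table: pd.DataFrame, constants: ConversionConstants | None = None
) -> pd.DataFrame:
    """Apply the per-cell conversion to a glycerol assay table.

    Expects columns ``concentration_ng_per_ul``, ``od600`` and ``vrel``;
    returns a copy with a ``pmol_per_cell`` column appended.
    """
    constants = constants or ConversionConstants()
    out = table.copy()
    out["pmol_per_cell"] = [
        extracellular_per_cell(c, o, v, constants)
        for c, o, v in zip(out["concentration_ng_per_ul"], out["od600"], out["vrel"])
    ]
    return out
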