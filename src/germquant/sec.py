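"""Analytical size-exclusion chromatography calibration and oligomer calls.

A protein's partition coefficient on a gel-filtration column,

    Kav = (Ve - Vo) / (Vt - Vo),

is linearly related to the logarithm of its molecular weight, provided the
sample resembles the calibration standards in surface chemistry and shape.
``Ve`` is the retention volume, ``Vo`` the void volume and ``Vt`` the total
column volume (0.86 mL and 2.4 mL for a Superose 6 PC 3.2/30).  Fitting
log10(MW) against Kav for a standards kit gives a per-buffer calibration
line; evaluating it at a sample's Kav yields the apparent MW, whose ratio
to the sequence-derived monomer MW supports a monomer/dimer/higher call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ColumnSpec",
    "CalibrationCurve",
    "OligomerCall",
    "SUPEROSE_6_PC_3230",
    "kav",
    "fit_calibration",
    "apparent_mw",
    "call_oligomer",
]


@dataclass(frozen=True)
class ColumnSpec:
    """Void (v0) and total (vt) volumes of a gel-filtration column, in mL."""

    v0: float
    vt: float

    def __post_init__(self) -> None:
        if not 0 < self.v0 < self.vt:
            raise ValueError(f"need 0 < v0 < vt, got v0={self.v0}, vt={self.vt}")


#: Superose 6 PC 3.2/30: void 0.86 mL, total 2.4 mL.
SUPEROSE_6_PC_3230 = ColumnSpec(v0=0.86, vt=2.4)


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line log10(MW [kDa]) = slope * Kav + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_standards: int


@dataclass(frozen=True)
class OligomerCall:
    """Apparent-MW-based oligomeric state assignment.

    ``ratio`` = apparent / monomer MW; the state is the nearest integer
    multiple under the configured cut-points (default: < 1.5 monomer,
    1.5-2.5 dimer, else higher).
    """

    apparent_mw: float
    monomer_mw: float
    ratio: float
    state: str


def kav(ve: float, column: ColumnSpec) -> float:
    """Partition coefficient (Ve - Vo)/(Vt - Vo).

    Values outside [0, 1] indicate anomalous elution (aggregation in the
    void, or matrix interaction) and draw a warning, not an error.
    """
    k = (ve - column.v0) / (column.vt - column.v0)
    if not 0 <= k <= 1:
        warnings.warn(
            f"Kav = {k:.3f} outside [0, 1]: anomalous elution at Ve = {ve} mL",
            stacklevel=2,
        )
    return k


def fit_calibration(
    standards: list[tuple[float, float]], column: ColumnSpec = SUPEROSE_6_PC_3230
) -> CalibrationCurve:
    """Fit log10(MW) on Kav by ordinary least squares.

    ``standards`` is a list of ``(ve_mL, mw_kDa)`` pairs; at least two with
    distinct Kav are required.
    """
    if len(standards) < 2:
        raise ValueError("need at least 2 standards")
    ves = np.array([s[0] for s in standards], dtype=np.float64)
    mws = np.array([s[1] for s in standards], dtype=np.float64)
    if (mws <= 0).any():
        raise ValueError("standard MWs must be positive")
    kavs = (ves - column.v0) / (column.vt - column.v0)
    if np.ptp(kavs) == 0:
        raise ValueError("standards have identical Kav; line is degenerate")
    fit = stats.linregress(kavs, np.log10(mws))
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_standards=len(standards),
    )


def apparent_mw(
    curve: CalibrationCurve, ve: float, column: ColumnSpec = SUPEROSE_6_PC_3230
) -> float:
    """Apparent MW (kDa) of a sample eluting at ``ve`` mL: 10**(m*Kav + b)."""
    return float(10 ** (curve.slope * kav(ve, column) + curve.intercept))


def call_oligomer(
    apparent: float,
    monomer_mw: float,
    cut_points: tuple[float, float] = (1.5, 2.5),
) -> OligomerCall:
    """Assign monomer/dimer/higher from the apparent-to-monomer MW ratio.

    Nearest-integer-multiple rule: ratio below ``cut_points[0]`` is a
    monomer, between the cut points a dimer, above them a higher oligomer.
    """
    if apparent <= 0 or monomer_mw <= 0:
        raise ValueError("masses must be positive")
    lo, hi = cut_points
    if not 0 < lo < hi:
        raise ValueError("cut points must satisfy 0 < lo < hi")
    ratio = apparent / monomer_mw
    state = "monomer" if ratio < lo else ("dimer" if ratio < hi else "higher")
    return OligomerCall(
        apparent_mw=apparent, monomer_mw=monomer_mw, ratio=ratio, state=state
    )
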