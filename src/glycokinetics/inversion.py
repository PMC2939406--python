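"""Inversion of the mixture model and error analysis of naive conversion.

The mixed HbA1c measured m months after a change in glycemic control is an
affine function of the new curve's steady-state HbA1c, so the inversion is
closed-form::

    Hb_x = [16 Hb_mix - Hb_1 (m^2 - 8m + 16)] / (8m - m^2)

recovering the glycemic curve the patient actually moved to -- the quantity
an "early" HbA1c measurement cannot show directly.  The denominator is
positive on (0, 4], so the inversion is defined for every admissible elapsed
time.  Results that are algebraically valid but physiologically impossible
(Hb_x <= 0, MPG_x <= 0) are flagged, never clamped or raised: such regimes
legitimately appear in error tabulations.

Converting the measured Hb_mix to glucose with the steady-state formula alone
("crude" conversion) ignores the old-curve survivors still circulating; the
relative error of that shortcut is::

    error = 100 * (MPG_real - MPG_crude) / MPG_real

with MPG_real the model-recovered MPG_x.  Negative errors mean the crude
method overestimates glycemia, positive errors underestimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conversion import ConversionModel, DCCT, InterceptMode, hba1c_from_mpg, mpg_from_hba1c
from .kinetics import LIFESPAN_MONTHS, hb_mix_formula, _check_m

__all__ = [
    "NON_PHYSIOLOGICAL",
    "InversionResult",
    "TimeCourse",
    "ErrorEstimate",
    "ErrorGrid",
    "invert_hbx",
    "invert_mpgx",
    "percent_change",
    "time_course",
    "estimation_error",
    "error_grid",
    "TABLE_MPG1_ANCHORS",
    "TABLE_HBMIX_ANCHORS",
]

NON_PHYSIOLOGICAL = "non-physiological"

#: Default error-grid anchors: MPG1 at the DCCT anchors of 5..12% HbA1c plus
#: two higher glycemia columns, measured Hb_mix at integer percents 5..14.
TABLE_MPG1_ANCHORS: tuple[float, ...] = (101, 137, 172, 208, 244, 279, 315, 350, 385, 420)
TABLE_HBMIX_ANCHORS: tuple[float, ...] = (5, 6, 7, 8, 9, 10, 11, 12, 13, 14)


def _weights(m: float) -> tuple[float, float]:
    return 8.0 * m - m**2, m**2 - 8.0 * m + 16.0


@dataclass(frozen=True)
class InversionResult:
    """Recovered new-curve state with its glucose twin and warning flags."""

    hbx: float
    mpgx: float | None
    hb_mix_input: float
    m: float
    hb1: float | None = None
    mpg1: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def non_physiological(self) -> bool:
        return NON_PHYSIOLOGICAL in self.flags


def invert_hbx(
    hb_mix: float,
    hb1: float,
    m: float,
    model: ConversionModel = DCCT,
    intercept_mode: InterceptMode = "paper",
) -> InversionResult:
    """Recover the new curve's steady HbA1c from an early measurement.

    Exact algebraic inverse of the forward mixture: feeding the result back
    through the mixture with the same (hb1, m) reproduces ``hb_mix``.
    A non-positive result is flagged, not raised, and its MPG twin is left
    undefined (the conversion has no physiological meaning there).
    """
    _check_m(m, exclusive_zero=True)
    new_w, old_w = _weights(m)
    hbx = (16.0 * hb_mix - hb1 * old_w) / new_w
    flags: tuple[str, ...] = ()
    mpgx: float | None = None
    if hbx <= model.min_hba1c:
        flags = (NON_PHYSIOLOGICAL,)
    else:
        mpgx = mpg_from_hba1c(hbx, model, intercept_mode)
    return InversionResult(
        hbx=hbx, mpgx=mpgx, hb_mix_input=hb_mix, m=m, hb1=hb1, flags=flags
    )


def invert_mpgx(
    hb_mix: float,
    mpg1: float,
    m: float,
    constant_mode: str = "paper",
    model: ConversionModel = DCCT,
    intercept_mode: InterceptMode = "paper",
) -> InversionResult:
    """Recover the new curve's MPG (mg/dl) from an early measurement.

    ``constant_mode="paper"`` uses the published MPG-space constants::

        MPG_x = [570 Hb_mix - MPG_1 (m^2 - 8m + 16) - 1236] / (8m - m^2)

    ``constant_mode="exact"`` composes :func:`invert_hbx` with the conversion
    model.  MPG_x <= 0 is flagged, not raised.
    """
    _check_m(m, exclusive_zero=True)
    new_w, old_w = _weights(m)
    if constant_mode == "paper":
        mpgx = (570.0 * hb_mix - mpg1 * old_w - 1236.0) / new_w
        hbx = hba1c_from_mpg(mpgx, model, intercept_mode) if mpgx > 0 else np.nan
    elif constant_mode == "exact":
        hb1 = hba1c_from_mpg(mpg1, model, intercept_mode)
        hbx = (16.0 * hb_mix - hb1 * old_w) / new_w
        mpgx = model.slope * hbx + model.intercept if model.has_formula else np.nan
    else:
        raise ValueError(f"unknown constant mode {constant_mode!r}")
    flags = (NON_PHYSIOLOGICAL,) if mpgx <= 0 else ()
    return InversionResult(
        hbx=float(hbx), mpgx=float(mpgx), hb_mix_input=hb_mix, m=m, mpg1=mpg1, flags=flags
    )


def percent_change(m: float) -> float:
    """Percent of the total HbA1c transition completed by month ``m``.

    100 * (8m - m^2) / 16 -- independent of the endpoints hb1, hbx because
    they cancel in (hb1 - hb_mix(m)) / (hb1 - hbx).
    """
    _check_m(m)
    return 100.0 * (8.0 * m - m**2) / 16.0


@dataclass(frozen=True)
class TimeCourse:
    """Sampled transition of measured HbA1c after a step change."""

    hb1: float
    hbx: float
    grid: np.ndarray
    hb_mix_values: np.ndarray
    percent_complete: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m_months": self.grid,
                "hb_mix_percent": self.hb_mix_values,
                "percent_complete": self.percent_complete,
            }
        )


#: Default sampling grid for time courses: 0.1-month steps over (0, 4].
DEFAULT_TIME_GRID = np.round(np.arange(0.1, LIFESPAN_MONTHS + 1e-9, 0.1), 10)


def time_course(hb1: float, hbx: float, grid=None) -> TimeCourse:
    """Evaluate the mixture and percent-complete on a grid of elapsed months."""
    grid = DEFAULT_TIME_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid must be non-empty")
    if np.any(grid <= 0) or np.any(grid > LIFESPAN_MONTHS):
        raise ValueError(f"grid values must lie in (0, {LIFESPAN_MONTHS}] months")
    values = hb_mix_formula(hb1, hbx, grid)
    complete = 100.0 * (8.0 * grid - grid**2) / 16.0
    return TimeCourse(
        hb1=hb1, hbx=hbx, grid=grid, hb_mix_values=values, percent_complete=complete
    )


@dataclass(frozen=True)
class ErrorEstimate:
    """Relative error (%) of crude Hb_mix -> MPG conversion, with context."""

    error: float
    mpgx: float
    mpg_crude: float
    flags: tuple[str, ...] = ()

    def __float__(self) -> float:
        return self.error


def estimation_error(
    hb_mix: float,
    mpg1: float,
    m: float,
    constant_mode: str = "paper",
    model: ConversionModel = DCCT,
    intercept_mode: InterceptMode = "paper",
) -> ErrorEstimate:
    """Percent error of converting ``hb_mix`` to glucose as if at steady state.

    Returns ``100 * (1 - MPG_crude / MPG_x)`` where the crude value applies
    the steady-state forward formula to ``hb_mix`` and MPG_x comes from
    :func:`invert_mpgx`.  A non-physiological MPG_x is carried through in the
    flags; the ratio is still reported when it is finite.
    """
    inv = invert_mpgx(hb_mix, mpg1, m, constant_mode, model, intercept_mode)
    crude = model.slope * hb_mix + model.intercept  # type: ignore[operator]
    mpgx = inv.mpgx if inv.mpgx is not None else np.nan
    error = np.nan if mpgx == 0 else 100.0 * (1.0 - crude / mpgx)
    return ErrorEstimate(error=float(error), mpgx=float(mpgx), mpg_crude=crude, flags=inv.flags)


@dataclass(frozen=True)
class ErrorGrid:
    """Crude-conversion error (%) tabulated over (Hb_mix, MPG1) anchors.

    Rows are measured Hb_mix values, columns initial MPG1 values.  ``mask``
    marks cells whose implied new-curve HbA1c leaves the plausibility
    envelope; such cells are suppressed in exported tables.
    """

    m: float
    mpg1_values: np.ndarray
    hbmix_values: np.ndarray
    cells: np.ndarray
    mask: np.ndarray
    hbx_bounds: tuple[float, float] = (0.0, 20.0)

    def to_frame(self, masked_as_nan: bool = True) -> pd.DataFrame:
        cells = np.where(self.mask, np.nan, self.cells) if masked_as_nan else self.cells
        return pd.DataFrame(
            cells,
            index=pd.Index(self.hbmix_values, name="hb_mix_percent"),
            columns=pd.Index(self.mpg1_values, name="mpg1_mg_dl"),
        )

    def to_csv(self, path) -> None:
        # masked cells serialize as empty fields, matching a blanked table
        self.to_frame().to_csv(path)


def error_grid(
    m: float,
    mpg1_values=TABLE_MPG1_ANCHORS,
    hbmix_values=TABLE_HBMIX_ANCHORS,
    constant_mode: str = "paper",
    hbx_bounds: tuple[float, float] = (0.0, 20.0),
    model: ConversionModel = DCCT,
    intercept_mode: InterceptMode = "paper",
) -> ErrorGrid:
    """Tabulate :func:`estimation_error` over a grid of anchors.

    A cell is masked when the implied new-curve HbA1c falls outside
    ``hbx_bounds`` (default [0, 20]%), or when the recovered MPG_x is
    non-positive -- regimes where the scenario itself is implausible and the
    tabulated error meaningless.
    """
    _check_m(m, exclusive_zero=True)
    mpg1_values = np.asarray(mpg1_values, dtype=float)
    hbmix_values = np.asarray(hbmix_values, dtype=float)
    if mpg1_values.size == 0 or hbmix_values.size == 0:
        raise ValueError("grid anchors must be non-empty")
    cells = np.empty((hbmix_values.size, mpg1_values.size))
    mask = np.zeros_like(cells, dtype=bool)
    lo, hi = hbx_bounds
    for i, hmix in enumerate(hbmix_values):
        for j, mpg1 in enumerate(mpg1_values):
            est = estimation_error(hmix, mpg1, m, constant_mode, model, intercept_mode)
            cells[i, j] = est.error
            hb1 = hba1c_from_mpg(mpg1, model, intercept_mode)
            implied_hbx = invert_hbx(hmix, hb1, m, model, intercept_mode).hbx
            mask[i, j] = (
                not (lo <= implied_hbx <= hi)
                or NON_PHYSIOLOGICAL in est.flags
                or not np.isfinite(est.error)
            )
    return ErrorGrid(
        m=m,
        mpg1_values=mpg1_values,
        hbmix_values=hbmix_values,
        cells=cells,
        mask=mask,
        hbx_bounds=hbx_bounds,
    )
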