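"""Linear HbA1c <-> mean plasma glucose (MPG) mappings and tabulated anchors.

The DCCT regression relates laboratory HbA1c (%) to the time-averaged plasma
glucose it reflects::

    MPG (mg/dl) = 35.6 * HbA1c - 77.3

and its printed inverse::

    HbA1c (%) = MPG / 35.6 + 2.17

The printed inverse intercept 2.17 is a rounding of 77.3 / 35.6 = 2.17134...,
so the forward and printed-inverse maps are not exact inverses of each other.
Two intercept modes are therefore exposed:

``"paper"``
    the inverse uses the printed 2.17, reproducing every number a clinician
    would obtain from the published formulas (default);
``"exact"``
    the inverse uses 77.3 / 35.6, making forward/inverse a true round trip.

The ADAG (A1c-Derived Average Glucose) relationship is available only as
tabulated anchors between 5% and 12% HbA1c; queries between anchors are
linearly interpolated, and no formula is extrapolated beyond them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConversionModel",
    "DCCT",
    "ADAG",
    "MODELS",
    "InterceptMode",
    "mpg_from_hba1c",
    "hba1c_from_mpg",
    "reference_table",
    "reference_mpg",
    "write_reference_csv",
    "round_half_away",
    "MMOL_L_TO_MG_DL",
]

InterceptMode = Literal["paper", "exact"]

#: mmol/l -> mg/dl factor for glucose (molar mass 180.16 g/mol).  Table anchors
#: store both units verbatim; the factor is provided for callers, the anchors
#: are never recomputed from it.
MMOL_L_TO_MG_DL = 18.016


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (clinical-table convention, unlike banker's)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConversionModel:
    """A named HbA1c<->MPG relationship.

    ``slope``/``intercept`` define the forward linear map MPG = slope*HbA1c +
    intercept in mg/dl; models published only as a table (ADAG) carry ``None``
    and fall back to monotone linear interpolation through their anchors.

    ``reference_rows`` are (hba1c %, mpg mmol/l, mpg mg/dl) anchors stored
    verbatim from the source table.
    """

    name: str
    slope: float | None
    intercept: float | None
    reference_rows: tuple[tuple[float, float, float], ...]
    paper_inverse_offset: float | None = None

    def __post_init__(self) -> None:
        if self.slope is not None and self.slope <= 0:
            raise ValueError(f"{self.name}: slope must be positive")

    @property
    def has_formula(self) -> bool:
        return self.slope is not None

    @property
    def min_hba1c(self) -> float:
        """Smallest HbA1c mapping to a positive MPG under the forward formula."""
        if not self.has_formula:
            return self.reference_rows[0][0]
        return -self.intercept / self.slope  # type: ignore[operator]

    def _anchor_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        rows = np.asarray(self.reference_rows, dtype=float)
        return rows[:, 0], rows[:, 2]

    def mpg_from_hba1c(self, hba1c: float, mode: InterceptMode = "paper") -> float:
        if self.has_formula:
            mpg = self.slope * hba1c + self.intercept  # type: ignore[operator]
            if mpg <= 0:
                raise ValueError(
                    f"HbA1c {hba1c}% maps to non-positive MPG under {self.name}; "
                    f"minimum representable HbA1c is {self.min_hba1c:.4f}%"
                )
            return mpg
        h, g = self._anchor_arrays()
        if not (h[0] <= hba1c <= h[-1]):
            raise ValueError(
                f"{self.name} is tabulated only for HbA1c in [{h[0]}, {h[-1]}]%"
            )
        return float(np.interp(hba1c, h, g))

    def hba1c_from_mpg(self, mpg: float, mode: InterceptMode = "paper") -> float:
        if mpg <= 0:
            raise ValueError("MPG must be positive (mg/dl)")
        if self.has_formula:
            offset = (
                self.paper_inverse_offset
                if (mode == "paper" and self.paper_inverse_offset is not None)
                else -self.intercept / self.slope  # type: ignore[operator]
            )
            return mpg / self.slope + offset  # type: ignore[operator]
        h, g = self._anchor_arrays()
        if not (g[0] <= mpg <= g[-1]):
            raise ValueError(
                f"{self.name} is tabulated only for MPG in [{g[0]}, {g[-1]}] mg/dl"
            )
        return float(np.interp(mpg, g, h))


# DCCT seven-point-profile regression, anchors tabulated at integer HbA1c.
DCCT = ConversionModel(
    name="DCCT",
    slope=35.6,
    intercept=-77.3,
    paper_inverse_offset=2.17,
    reference_rows=(
        (5, 5.6, 101),
        (6, 7.6, 137),
        (7, 9.6, 172),
        (8, 11.5, 208),
        (9, 13.5, 244),
        (10, 15.5, 279),
        (11, 17.5, 315),
        (12, 19.5, 350),
    ),
)

# ADAG continuous-glucose-monitoring anchors; published here as a table only.
ADAG = ConversionModel(
    name="ADAG",
    slope=None,
    intercept=None,
    reference_rows=(
        (5, 5.4, 97),
        (6, 7.0, 126),
        (7, 8.6, 154),
        (8, 10.2, 183),
        (9, 11.8, 212),
        (10, 13.4, 240),
        (11, 14.9, 269),
        (12, 16.5, 298),
    ),
)

MODELS: dict[str, ConversionModel] = {"DCCT": DCCT, "ADAG": ADAG}


def mpg_from_hba1c(
    hba1c: float, model: ConversionModel = DCCT, mode: InterceptMode = "paper"
) -> float:
    """Forward map HbA1c (%) -> MPG (mg/dl). No rounding is applied."""
    return model.mpg_from_hba1c(hba1c, mode)


def hba1c_from_mpg(
    mpg: float, model: ConversionModel = DCCT, mode: InterceptMode = "paper"
) -> float:
    """Inverse map MPG (mg/dl) -> HbA1c (%).

    In ``"paper"`` mode the DCCT inverse uses the printed intercept 2.17; in
    ``"exact"`` mode it is the true algebraic inverse of :func:`mpg_from_hba1c`.
    """
    return model.hba1c_from_mpg(mpg, mode)


def reference_table(model: ConversionModel = DCCT) -> pd.DataFrame:
    """Tabulated (hba1c_percent, mpg_mmol_l, mpg_mg_dl) anchors, verbatim."""
    frame = pd.DataFrame(
        list(model.reference_rows),
        columns=["hba1c_percent", "mpg_mmol_l", "mpg_mg_dl"],
    )
    frame["model"] = model.name
    return frame


def reference_mpg(
    model: ConversionModel, hba1c: float, interpolate: bool = False
) -> float:
    """Look up the tabulated MPG (mg/dl) anchor at ``hba1c``.

    With ``interpolate=True`` a query between anchors is linearly
    interpolated; queries outside the tabulated range raise.
    """
    h, g = model._anchor_arrays()
    if not (h[0] <= hba1c <= h[-1]):
        raise ValueError(
            f"query {hba1c}% outside the tabulated range [{h[0]}, {h[-1]}]%"
        )
    exact = np.flatnonzero(np.isclose(h, hba1c))
    if exact.size:
        return float(g[exact[0]])
    if not interpolate:
        raise KeyError(f"{hba1c}% is not a tabulated anchor of {model.name}")
    return float(np.interp(hba1c, h, g))


def write_reference_csv(
    path, models: Sequence[ConversionModel] | Iterable[ConversionModel] = (DCCT, ADAG)
) -> pd.DataFrame:
    """Write the reference anchors of ``models`` to a single CSV."""
    frame = pd.concat([reference_table(m) for m in models], ignore_index=True)
    frame.to_csv(path, index=False)
    return frame
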