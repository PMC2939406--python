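"""Per-erythrocyte glycation law, cohort averaging and the two-curve mixture.

Hemoglobin glycation is continuous, nonenzymatic and essentially irreversible,
so a single erythrocyte living at constant mean plasma glucose accumulates
HbA1c linearly with age: zero at birth, and at the full 120-day (4-month)
lifespan exactly twice the steady-state HbA1c its glucose level sustains.
Because erythropoiesis balances destruction, cell ages are uniform on
[0, 4] months and the circulating mean is the arithmetic mean of the youngest
and oldest cells -- which is what the laboratory assay measures.

After a step change in glycemic control at time 0, the circulating population
m months later is a mixture of two groups:

* survivors of the old curve (fraction (4-m)/4), carrying their old glycation
  plus m months of accrual at the new rate;
* cells born after the change (fraction m/4), glycated only on the new curve.

Averaging the groups gives the measured mixed HbA1c

    Hb_mix = [Hb_x (8m - m^2) + Hb_1 (m^2 - 8m + 16)] / 16

where Hb_1 and Hb_x are the steady-state HbA1c of the old and new curves.
This Hb-space form is the canonical implementation: it involves no
HbA1c<->glucose conversion at all.  The equivalent MPG-space form (with the
published constants 570 and 1236, or their exact counterparts) is provided
for reproducing published tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conversion import ConversionModel, DCCT, InterceptMode, hba1c_from_mpg, mpg_from_hba1c

__all__ = [
    "LIFESPAN_MONTHS",
    "GlycationCurve",
    "MixtureScenario",
    "curve_value",
    "cohort_mean_steady",
    "phi_upper",
    "phi_mean",
    "delta_phi_mean",
    "phi1",
    "phi2",
    "hb_mix",
    "hb_mix_formula",
    "hb_mix_from_mpg",
]

#: Erythrocyte lifespan; one model month is 30 days, the lifespan 120 days.
LIFESPAN_MONTHS = 4.0


def _check_m(m: float, *, exclusive_zero: bool = False) -> None:
    lo_ok = m > 0 if exclusive_zero else m >= 0
    if not (lo_ok and m <= LIFESPAN_MONTHS):
        lo = "(0" if exclusive_zero else "[0"
        raise ValueError(
            f"elapsed time m={m} months outside {lo}, {LIFESPAN_MONTHS}] "
            "(erythrocytes do not outlive their lifespan)"
        )


@dataclass(frozen=True)
class GlycationCurve:
    """Linear HbA1c-accumulation law of a cell living at constant glucose.

    ``steady_hba1c`` is the circulating-mean HbA1c this glucose level
    sustains at steady state; a single cell reaches twice that value at the
    end of its 4-month life.
    """

    mpg: float
    steady_hba1c: float

    @classmethod
    def from_mpg(
        cls, mpg: float, model: ConversionModel = DCCT, mode: InterceptMode = "paper"
    ) -> "GlycationCurve":
        return cls(mpg=mpg, steady_hba1c=hba1c_from_mpg(mpg, model, mode))

    @classmethod
    def from_steady_hba1c(
        cls, hba1c: float, model: ConversionModel = DCCT, mode: InterceptMode = "paper"
    ) -> "GlycationCurve":
        return cls(mpg=mpg_from_hba1c(hba1c, model, mode), steady_hba1c=hba1c)


def curve_value(curve: GlycationCurve, m: float) -> float:
    """Accumulated HbA1c (%) of a single cell aged ``m`` months on ``curve``."""
    _check_m(m)
    return curve.steady_hba1c * m / 2.0


def cohort_mean_steady(curve: GlycationCurve) -> float:
    """Circulating-mean HbA1c at steady state: mean of youngest and oldest."""
    return (curve_value(curve, 0.0) + curve_value(curve, LIFESPAN_MONTHS)) / 2.0


@dataclass(frozen=True)
class MixtureScenario:
    """One step-change episode: old curve ``hb1``, new curve ``hbx``, elapsed ``m``.

    ``hb1`` and ``hbx`` are steady-state HbA1c (%) of the glycemic curves
    before and after the change; ``m`` is months since the change, 0 < m <= 4.
    MPG-space twins are attached at construction under the chosen conversion
    model and never re-derived afterwards.
    """

    hb1: float
    hbx: float
    m: float
    mpg1: float | None = None
    mpgx: float | None = None

    def __post_init__(self) -> None:
        _check_m(self.m, exclusive_zero=True)
        if self.hb1 <= 0 or self.hbx <= 0:
            raise ValueError("steady-state HbA1c values must be positive")

    @classmethod
    def from_hba1c(
        cls,
        hb1: float,
        hbx: float,
        m: float,
        model: ConversionModel = DCCT,
        mode: InterceptMode = "paper",
    ) -> "MixtureScenario":
        return cls(
            hb1=hb1,
            hbx=hbx,
            m=m,
            mpg1=mpg_from_hba1c(hb1, model, mode),
            mpgx=mpg_from_hba1c(hbx, model, mode),
        )

    @classmethod
    def from_mpg(
        cls,
        mpg1: float,
        mpgx: float,
        m: float,
        model: ConversionModel = DCCT,
        mode: InterceptMode = "paper",
    ) -> "MixtureScenario":
        """Build from MPG inputs, converting to Hb-space once at construction."""
        return cls(
            hb1=hba1c_from_mpg(mpg1, model, mode),
            hbx=hba1c_from_mpg(mpgx, model, mode),
            m=m,
            mpg1=mpg1,
            mpgx=mpgx,
        )


def phi_upper(scenario: MixtureScenario) -> float:
    """Highest HbA1c among surviving old-curve cells, hb1*(4-m)/2.

    The oldest survivor was (4-m) months old at the change; its accumulated
    HbA1c is the old curve evaluated there.
    """
    return scenario.hb1 * (LIFESPAN_MONTHS - scenario.m) / 2.0


def phi_mean(scenario: MixtureScenario) -> float:
    """Pre-change mean HbA1c of the surviving old cells, hb1*(4-m)/4."""
    return phi_upper(scenario) / 2.0


def delta_phi_mean(scenario: MixtureScenario) -> float:
    """New glycation accrued by the survivors on the new curve, hbx*m/2."""
    return scenario.hbx * scenario.m / 2.0


def phi1(scenario: MixtureScenario) -> float:
    """Total mean HbA1c of the old-cell group: old glycation plus new accrual."""
    return phi_mean(scenario) + delta_phi_mean(scenario)


def phi2(scenario: MixtureScenario) -> float:
    """Mean HbA1c of cells born after the change, hbx*m/4."""
    return scenario.hbx * scenario.m / 4.0


def hb_mix_formula(hb1, hbx, m):
    """Vectorised mixed-HbA1c closed form; no domain checks (internal)."""
    m = np.asarray(m, dtype=float)
    return (hbx * (8.0 * m - m**2) + hb1 * (m**2 - 8.0 * m + 16.0)) / 16.0


def hb_mix(scenario: MixtureScenario) -> float:
    """Measured HbA1c ``m`` months after the step change (Hb-space form).

    Equals the age-weighted average of the two groups,
    ``(phi2*m + phi1*(4-m)) / 4``, exactly.
    """
    return float(hb_mix_formula(scenario.hb1, scenario.hbx, scenario.m))


def hb_mix_from_mpg(
    mpg1: float,
    mpgx: float,
    m: float,
    constant_mode: str = "paper",
    model: ConversionModel = DCCT,
    intercept_mode: InterceptMode = "paper",
) -> float:
    """Mixed HbA1c from MPG-space inputs.

    ``constant_mode="paper"`` uses the published rounded constants::

        Hb_mix = [MPG_x (8m - m^2) + MPG_1 (m^2 - 8m + 16) + 1236] / 570

    ``constant_mode="exact"`` converts both glucose levels to Hb-space through
    ``model`` and evaluates the canonical Hb-space form.
    """
    _check_m(m, exclusive_zero=True)
    if constant_mode == "paper":
        return (mpgx * (8.0 * m - m**2) + mpg1 * (m**2 - 8.0 * m + 16.0) + 1236.0) / 570.0
    if constant_mode == "exact":
        scenario = MixtureScenario.from_mpg(mpg1, mpgx, m, model, intercept_mode)
        return hb_mix(scenario)
    raise ValueError(f"unknown constant mode {constant_mode!r}")
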