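"""Discrete age-structured erythrocyte cohort simulator.

The circulating red-cell population is modelled as 120 equal-mass daily age
cohorts: each day 1/120 of the mass is born and the 120-day-old cohort is
destroyed, so the age distribution is uniform and stationary.  Every cohort
accumulates HbA1c at a rate set by that day's plasma glucose only
(piecewise-constant forcing); glycation never reverses while a cell lives.

The daily increment for glucose level sustaining steady HbA1c ``h`` is
``h / 60``: a cell then reaches ``2 h`` over its 120-day life and the
population mean is ``h``, matching the continuous arithmetic-mean result.
Cohort values are evaluated at mid-day ages (age + 0.5 days) so the discrete
steady-state mean equals the continuous one exactly rather than with
O(1/120) bias.

The model is deterministic throughout -- there is no randomness to seed.
The simulator serves as a brute-force oracle for every closed form in
:mod:`glycokinetics.kinetics` and generalises the model to arbitrary daily
glucose trajectories, which the closed forms cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .conversion import ConversionModel, DCCT, InterceptMode, hba1c_from_mpg

__all__ = [
    "LIFESPAN_DAYS",
    "DAYS_PER_MONTH",
    "CohortPopulation",
    "MpgTrajectory",
    "init_steady_state",
    "init_steady_state_hb",
    "step",
    "step_hb",
    "mean_hba1c",
    "simulate",
    "simulate_hb",
    "read_trajectory_csv",
    "write_series_csv",
]

LIFESPAN_DAYS = 120
DAYS_PER_MONTH = 30


def _daily_increment(steady_hba1c: float) -> float:
    # steady mean h  <=>  per-cell slope 2h per lifespan  <=>  h/60 per day
    return steady_hba1c / 60.0


@dataclass(frozen=True)
class CohortPopulation:
    """Accumulated HbA1c (%) of the 120 daily age cohorts, youngest first."""

    cohort_hba1c: np.ndarray
    day: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.cohort_hba1c, dtype=float)
        if arr.shape != (LIFESPAN_DAYS,):
            raise ValueError(f"population must hold exactly {LIFESPAN_DAYS} cohorts")
        object.__setattr__(self, "cohort_hba1c", arr)


@dataclass(frozen=True)
class MpgTrajectory:
    """Daily mean-plasma-glucose forcing (mg/dl per simulation day)."""

    daily_mpg: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.daily_mpg, dtype=float)
        if arr.size == 0:
            raise ValueError("trajectory must be non-empty")
        if np.any(arr <= 0):
            raise ValueError("all trajectory MPG values must be positive")
        object.__setattr__(self, "daily_mpg", arr)

    @classmethod
    def constant(cls, mpg: float, days: int) -> "MpgTrajectory":
        return cls(np.full(days, float(mpg)))


def init_steady_state_hb(steady_hba1c: float) -> CohortPopulation:
    """Steady-state population for a glucose level given by its steady HbA1c."""
    if steady_hba1c <= 0:
        raise ValueError("steady HbA1c must be positive")
    rate = _daily_increment(steady_hba1c)
    ages = np.arange(LIFESPAN_DAYS, dtype=float)  # completed days of age
    return CohortPopulation(cohort_hba1c=(ages + 0.5) * rate, day=0)


def init_steady_state(
    mpg: float, model: ConversionModel = DCCT, mode: InterceptMode = "paper"
) -> CohortPopulation:
    """Population in glycation equilibrium with constant glucose ``mpg``.

    The cohort aged ``a`` completed days carries ``(a + 0.5)`` mid-days of
    accumulation; the population mean equals ``hba1c_from_mpg(mpg)`` exactly.
    """
    if mpg <= 0:
        raise ValueError("MPG must be positive (mg/dl)")
    return init_steady_state_hb(hba1c_from_mpg(mpg, model, mode))


def step_hb(pop: CohortPopulation, steady_hba1c_today: float) -> CohortPopulation:
    """Advance one day under glucose given by its steady-HbA1c equivalent."""
    if steady_hba1c_today <= 0:
        raise ValueError("steady HbA1c must be positive")
    rate = _daily_increment(steady_hba1c_today)
    aged = pop.cohort_hba1c + rate  # every surviving cell glycates today
    new = np.empty_like(aged)
    new[1:] = aged[:-1]  # ages shift by one day; the 120-day cohort dies
    new[0] = 0.5 * rate  # newborn cohort, half a day of accumulation
    return CohortPopulation(cohort_hba1c=new, day=pop.day + 1)


def step(
    pop: CohortPopulation,
    mpg_today: float,
    model: ConversionModel = DCCT,
    mode: InterceptMode = "paper",
) -> CohortPopulation:
    """Advance the population one day at glucose ``mpg_today`` (mg/dl)."""
    if mpg_today <= 0:
        raise ValueError("MPG must be positive (mg/dl)")
    return step_hb(pop, hba1c_from_mpg(mpg_today, model, mode))


def mean_hba1c(pop: CohortPopulation) -> float:
    """Circulating mean HbA1c (%): unweighted cohort mean (equal masses)."""
    return float(pop.cohort_hba1c.mean())


def simulate(
    trajectory: MpgTrajectory,
    init_mpg: float,
    model: ConversionModel = DCCT,
    mode: InterceptMode = "paper",
) -> pd.DataFrame:
    """Run the simulator day by day from steady state at ``init_mpg``.

    Returns a frame of (day, mean_hba1c) with one row per simulated day;
    day counts from 1 (the state after the first step).
    """
    pop = init_steady_state(init_mpg, model, mode)
    days, means = [], []
    for mpg_today in trajectory.daily_mpg:
        pop = step(pop, float(mpg_today), model, mode)
        days.append(pop.day)
        means.append(mean_hba1c(pop))
    return pd.DataFrame({"day": days, "mean_hba1c": means})


def simulate_hb(steady_hb_series, init_steady_hb: float) -> pd.DataFrame:
    """Hb-space driver: forcing given directly as daily steady-HbA1c values."""
    pop = init_steady_state_hb(init_steady_hb)
    days, means = [], []
    for h in np.asarray(steady_hb_series, dtype=float):
        pop = step_hb(pop, float(h))
        days.append(pop.day)
        means.append(mean_hba1c(pop))
    return pd.DataFrame({"day": days, "mean_hba1c": means})


def read_trajectory_csv(path) -> MpgTrajectory:
    """Read a daily trajectory CSV with columns ``day`` and ``mpg_mg_dl``."""
    frame = pd.read_csv(path)
    missing = {"day", "mpg_mg_dl"} - set(frame.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    frame = frame.sort_values("day")
    return MpgTrajectory(daily_mpg=frame["mpg_mg_dl"].to_numpy(dtype=float))


def write_series_csv(frame: pd.DataFrame, path) -> None:
    """Write a (day, mean_hba1c) series as CSV."""
    frame.to_csv(path, index=False)
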