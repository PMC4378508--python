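"""Climate-driven life-history simulation.

Chains the bolting model, the seed-set thermal-time model and the dormancy
model into per-germination-date life histories: for each germination date
the simulator predicts bolting and first seed set, reads the seed
maturation temperature ``T_m`` off the climate (mean daily temperature over
the week ending at seed set), reads the imbibition temperature ``T_i`` off
the window after shedding, and evaluates the progeny germination
probability.  Sweeps over germination dates, warming scenarios (uniform
temperature shifts) and genotype cohort summaries (seed set spread over a
month) are built on top.

The headline emergent behaviour: winter-annual cohorts set seed when the
ambient temperature crosses the ~14 degC dormancy switch, and because
warmer climates advance seed set, the maturation temperature is buffered
against large differences in annual mean temperature.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from seedlife.climate import ClimateSeries, extend_cyclic
from seedlife.germination import GerminationParams, germination_probability
from seedlife.phenology import (
    BoltingModelConfig,
    ThermalModelParams,
    predict_bolting,
    predict_seed_set,
)

__all__ = [
    "GenotypeConfig",
    "LifeHistoryResult",
    "CohortSummary",
    "working_series",
    "simulate_life_history",
    "annual_sweep",
    "seed_set_spread",
    "progeny_germination",
    "progeny_map",
    "cohort_summary",
    "warming_scenarios",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeConfig:
    """Everything genotype-specific: bolting, seed set and dormancy."""

    bolting: BoltingModelConfig
    seed_set: ThermalModelParams
    germination: GerminationParams
    label: str = "Col-0"


@dataclass(frozen=True)
class LifeHistoryResult:
    """One germination date's predicted life history."""

    germination_date: _dt.date
    bolting_date: _dt.date | None
    first_seed_set_date: _dt.date | None
    t_m: float | None
    status: Literal["completed", "did_not_complete"]

    def __post_init__(self) -> None:
        if self.status == "completed":
            if not (self.germination_date <= self.bolting_date <= self.first_seed_set_date):
                raise SimulationError("event ordering violated")


#: Trailing window (days, ending at shedding) defining the seed maturation
#: temperature; the final days before harvest dominate dormancy depth.
TM_WINDOW_DAYS = 7

#: Default evaluation horizon (days after shedding) for progeny germination;
#: matches the longest common incubation of the germination assays.
DEFAULT_HORIZON_DAYS = 28


def working_series(
    climate: ClimateSeries, start: _dt.date, horizon_days: int = 730
) -> ClimateSeries:
    """Resolve a climate argument into a dated series covering the horizon.

    A 365-day climatology (single synthetic year) is replicated cyclically
    from ``start``; an already-dated multi-year series is returned as is
    (accumulations that outrun it report did-not-complete).
    """
    if len(climate) == 365 and climate.start.year == climate.end.year:
        return extend_cyclic(climate, start, horizon_days)
    return climate


def _trailing_mean(climate: ClimateSeries, end: _dt.date, n_days: int) -> float:
    """Mean daily t_mean over the n_days ending at ``end`` (inclusive)."""
    days = [end - _dt.timedelta(days=i) for i in range(n_days)]
    return float(np.mean([climate.record_for(d).t_mean for d in days]))


def _leading_mean(climate: ClimateSeries, start: _dt.date, n_days: int) -> float:
    """Mean daily t_mean over [start, start + n_days)."""
    days = [start + _dt.timedelta(days=i) for i in range(n_days)]
    return float(np.mean([climate.record_for(d).t_mean for d in days]))


def simulate_life_history(
    climate: ClimateSeries,
    germination_date: _dt.date,
    genotype: GenotypeConfig,
    horizon_days: int = 730,
) -> LifeHistoryResult:
    """Predict bolting, first seed set and maturation temperature.

    The climatology is recycled over a two-year horizon; sowings whose
    bolting or seed-set accumulator is still short of threshold at the end
    of the horizon are reported ``did_not_complete`` (the far-north
    outcome), never raised.
    """
    series = working_series(climate, germination_date, horizon_days)
    incomplete = LifeHistoryResult(germination_date, None, None, None, "did_not_complete")
    bolting = predict_bolting(germination_date, series, genotype.bolting)
    if bolting is None or bolting > series.end:
        return incomplete
    seed_set = predict_seed_set(bolting, series, genotype.seed_set)
    if seed_set is None:
        return incomplete
    t_m = _trailing_mean(series, seed_set, TM_WINDOW_DAYS)
    return LifeHistoryResult(germination_date, bolting, seed_set, t_m, "completed")


def annual_sweep(
    climate: ClimateSeries,
    dates: Sequence[_dt.date],
    genotype: GenotypeConfig,
    horizon_days: int = 730,
) -> list[LifeHistoryResult]:
    """One life history per germination date, in input order."""
    return [simulate_life_history(climate, d, genotype, horizon_days) for d in dates]


def seed_set_spread(
    results: Iterable[LifeHistoryResult],
    window_start: _dt.date | None = None,
    window_end: _dt.date | None = None,
) -> float:
    """Convergence metric: sd (days) of first-seed-set dates in a window.

    Quantifies the funnelling of autumn-to-spring germination dates onto a
    narrow seed-set window.  Germination dates outside
    [window_start, window_end] and incomplete results are ignored.
    """
    ords = [
        r.first_seed_set_date.toordinal()
        for r in results
        if r.status == "completed"
        and (window_start is None or r.germination_date >= window_start)
        and (window_end is None or r.germination_date <= window_end)
    ]
    if len(ords) < 2:
        return np.nan
    return float(np.std(ords))


def progeny_germination(
    result: LifeHistoryResult,
    climate: ClimateSeries,
    params: GerminationParams,
    horizon_days: int = DEFAULT_HORIZON_DAYS,
) -> float:
    """Germination probability of the progeny of one life history.

    The imbibition temperature is the mean daily temperature over
    ``horizon_days`` after shedding and the dormancy model is evaluated at
    x = horizon_days.  At horizon 0 the x = 0 anchors give the fresh-seed
    probability 0.0099 regardless of temperature.
    """
    if result.status != "completed":
        raise SimulationError("progeny germination needs a completed life history")
    shed = result.first_seed_set_date
    series = working_series(climate, result.germination_date, 1095)
    if horizon_days == 0:
        t_i = series.record_for(shed).t_mean
    else:
        t_i = _leading_mean(series, shed, horizon_days)
    return float(germination_probability(horizon_days, result.t_m, t_i, params))


def progeny_map(
    results: Sequence[LifeHistoryResult],
    climate: ClimateSeries,
    params: GerminationParams,
    horizons: Sequence[int] = (7, 14, 28, 42),
) -> pd.DataFrame:
    """Long-format progeny-germination heat map.

    One row per (parental germination date, evaluation horizon) with the
    progeny germination fraction; incomplete parents yield NaN.
    """
    rows = []
    for r in results:
        for h in horizons:
            frac = (
                progeny_germination(r, climate, params, h)
                if r.status == "completed"
                else np.nan
            )
            rows.append(
                {"germination_date": r.germination_date, "horizon": h, "fraction": frac}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSummary:
    """Whole-progeny summary of a month-long seed-set window."""

    genotype: str
    first_seed_set_date: _dt.date
    mean_shedding_temperature: float
    mean_t_m: float
    fraction_low_dormant: float
    scheme: Literal["normal", "uniform"]
    weights: np.ndarray = field(repr=False, compare=False, default=None)


SEED_SET_SPAN_DAYS = 30


def _shedding_weights(scheme: str, n: int = SEED_SET_SPAN_DAYS) -> np.ndarray:
    if scheme == "uniform":
        w = np.full(n, 1.0 / n)
    elif scheme == "normal":
        # truncated normal over the month: mean mid-window, sd 7 d
        mu, sd = n / 2.0, 7.0
        a, b = (0.0 - mu) / sd, (n - mu) / sd
        centers = np.arange(n) + 0.5
        w = truncnorm.pdf(centers, a, b, loc=mu, scale=sd)
        w = w / w.sum()
    else:
        raise SimulationError(f"unknown shedding scheme {scheme!r}")
    return w


def cohort_summary(
    result: LifeHistoryResult,
    climate: ClimateSeries,
    params: GerminationParams,
    scheme: Literal["normal", "uniform"] = "normal",
    horizon_days: int = DEFAULT_HORIZON_DAYS,
    hard_cutoff: bool = False,
) -> CohortSummary:
    """Summarise a genotype's whole progeny over a month of seed set.

    Seed set is assumed to last 30 days from first seed set, with shedding
    spread either uniformly or as a truncated normal (mean day 15, sd 7).
    Each shedding date gets its own trailing-week T_m and post-shedding
    T_i; ``fraction_low_dormant`` is the shedding-weighted mean progeny
    germination probability (or, with ``hard_cutoff``, the weighted
    fraction of shedding dates with probability > 0.5).
    """
    if result.status != "completed":
        raise SimulationError("cohort summary needs a completed life history")
    series = working_series(climate, result.germination_date, 1095)
    w = _shedding_weights(scheme)
    sheds = [result.first_seed_set_date + _dt.timedelta(days=k) for k in range(len(w))]
    t_ms = np.array([_trailing_mean(series, d, TM_WINDOW_DAYS) for d in sheds])
    t_is = np.array([_leading_mean(series, d, max(horizon_days, 1)) for d in sheds])
    p = germination_probability(horizon_days, t_ms, t_is, params)
    frac = float(w @ (p > 0.5)) if hard_cutoff else float(w @ p)
    t_shed = np.array([series.record_for(d).t_mean for d in sheds])
    return CohortSummary(
        genotype="",
        first_seed_set_date=result.first_seed_set_date,
        mean_shedding_temperature=float(w @ t_shed),
        mean_t_m=float(w @ t_ms),
        fraction_low_dormant=frac,
        scheme=scheme,
        weights=w,
    )


def warming_scenarios(
    climate: ClimateSeries,
    deltas: Sequence[float],
    genotype: GenotypeConfig,
    sowing_date: _dt.date,
    scheme: Literal["normal", "uniform"] = "normal",
    horizon_days: int = DEFAULT_HORIZON_DAYS,
) -> pd.DataFrame:
    """Winter-annual outcomes under uniform warming/cooling offsets.

    For each delta the whole climate is shifted, the fixed autumn sowing is
    simulated, and the table reports first seed set date, maturation
    temperature and the cohort fraction of low-dormant progeny.
    """
    from seedlife.climate import shift_series

    rows = []
    for delta in deltas:
        shifted = shift_series(climate, delta)
        res = simulate_life_history(shifted, sowing_date, genotype)
        if res.status == "completed":
            summ = cohort_summary(res, shifted, genotype.germination, scheme, horizon_days)
            rows.append(
                {
                    "delta": delta,
                    "status": res.status,
                    "first_seed_set_date": res.first_seed_set_date,
                    "t_m": res.t_m,
                    "fraction_low_dormant": summ.fraction_low_dormant,
                }
            )
        else:
            rows.append(
                {
                    "delta": delta,
                    "status": res.status,
                    "first_seed_set_date": pd.NaT,
                    "t_m": np.nan,
                    "fraction_low_dormant": np.nan,
                }
            )
    return pd.DataFrame(rows)
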