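"""Thermal-time and photothermal-time accumulators for developmental phases.

Development from bolting to first seed set (and, through a pluggable
interface, from germination to bolting) is modelled as the accumulation of
thermal time: each hour with mean temperature ``T`` above a genotype base
temperature ``T_b`` contributes ``T - T_b`` degC h, hours at or below
``T_b`` contribute nothing, and the phase completes when the running total
reaches a fixed threshold ``T_h``.  A photothermal variant gates the hourly
increment by a binary daylight flag; it is retained for comparison even
though the plain thermal model fits seed-set better.

At constant ``T > T_b`` the model collapses to the closed form

    days to completion = T_h / (24 (T - T_b))

which is used for fitting constant-regime laboratory observations and as
an independent check on the hour-by-hour accumulator.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from seedlife.climate import ClimateSeries, hourly_series

__all__ = [
    "ThermalModelParams",
    "BoltingModelConfig",
    "SeedSetObservation",
    "SeedSetFit",
    "thermal_increment",
    "photothermal_increment",
    "accumulate_to_threshold",
    "predict_seed_set",
    "predict_bolting",
    "fit_seed_set_params",
    "constant_temperature_days",
]


class PhenologyError(ValueError):
    pass


@dataclass(frozen=True)
class ThermalModelParams:
    """Base temperature (degC) and accumulation threshold (degC h) of a phase."""

    t_b: float
    threshold: float
    mode: Literal["thermal", "photothermal"] = "thermal"

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_b):
            raise PhenologyError("t_b must be finite")
        if self.threshold <= 0:
            raise PhenologyError("threshold must be > 0")
        if self.mode not in ("thermal", "photothermal"):
            raise PhenologyError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class BoltingModelConfig:
    """Pluggable germination-to-bolting model.

    ``model`` selects the implementation:

    * ``"fixed"`` — a fixed duration of ``duration_days`` (test stub);
    * ``"generic"`` — the generic (photo)thermal accumulator with
      ``params``, optionally scaled by a vernalization multiplier.

    The vernalization hook multiplies each hourly increment by a
    piecewise-linear function of the cold hours (below ``cold_threshold``)
    accumulated so far: ``vernalization_table`` is a sequence of
    (cold_hours, multiplier) knots with multipliers in [0, 1].  Published
    genotype-specific bolting parameterizations are consumed through this
    interface as external configuration, never re-derived here.
    """

    model: str = "fixed"
    duration_days: int = 30
    params: ThermalModelParams | None = None
    cold_threshold: float = 4.0
    vernalization_table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.model not in ("fixed", "generic"):
            raise PhenologyError(f"unknown bolting model {self.model!r}")
        if self.model == "generic" and self.params is None:
            raise PhenologyError("generic bolting model requires params")
        if self.vernalization_table is not None:
            for _, m in self.vernalization_table:
                if not 0.0 <= m <= 1.0:
                    raise PhenologyError("vernalization multipliers must lie in [0, 1]")


@dataclass(frozen=True)
class SeedSetObservation:
    """Observed days from bolting to first seed set under one regime.

    Either a constant ``temperature`` (lab regime, with ``photoperiod``
    hours of light per day) or a ``climate`` series plus ``bolting_date``
    (field regime) must be given.
    """

    days: float
    temperature: float | None = None
    photoperiod: float = 16.0
    climate: ClimateSeries | None = None
    bolting_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise PhenologyError("observed days must be > 0")
        if self.temperature is None and (self.climate is None or self.bolting_date is None):
            raise PhenologyError("need a constant temperature or climate + bolting date")


def thermal_increment(t, t_b):
    """Thermal-time units for one hour: max(T - T_b, 0) degC h."""
    return np.maximum(np.asarray(t, dtype=float) - t_b, 0.0)


def photothermal_increment(t, t_b, daylight):
    """Photothermal units: the thermal increment gated by daylight."""
    return thermal_increment(t, t_b) * np.asarray(daylight, dtype=float)


def _increments(hourly: pd.DataFrame, params: ThermalModelParams) -> np.ndarray:
    if params.mode == "photothermal":
        return photothermal_increment(hourly["temp"].to_numpy(), params.t_b,
                                      hourly["daylight"].to_numpy())
    return thermal_increment(hourly["temp"].to_numpy(), params.t_b)


def accumulate_to_threshold(
    hourly: pd.DataFrame,
    start: pd.Timestamp | _dt.datetime,
    params: ThermalModelParams,
    multiplier: np.ndarray | None = None,
) -> pd.Timestamp | None:
    """First hour at which the running thermal-time sum reaches threshold.

    Returns the timestamp of that hour, or ``None`` when the series is
    exhausted first (the explicit did-not-complete outcome needed for
    far-north winter sowings; never an exception).  ``multiplier``
    optionally scales each hourly increment (vernalization hook).
    """
    start = pd.Timestamp(start)
    mask = hourly["time"].to_numpy() >= np.datetime64(start)
    if not mask.any():
        return None
    sub = hourly.loc[mask]
    inc = _increments(sub, params)
    if multiplier is not None:
        inc = inc * multiplier[mask]
    total = np.cumsum(inc)
    idx = int(np.searchsorted(total, params.threshold))
    if idx >= len(total):
        return None
    return pd.Timestamp(sub["time"].to_numpy()[idx])


def predict_seed_set(
    bolting_date: _dt.date,
    climate: ClimateSeries,
    params: ThermalModelParams,
) -> _dt.date | None:
    """Date of first seed set for a given bolting date, or None.

    The climate series is hourly-interpolated from bolting onwards and the
    seed-set accumulator run to threshold.  Callers needing a longer
    horizon should extend the series cyclically first (see
    :func:`seedlife.climate.extend_cyclic`).
    """
    hourly = hourly_series(climate, start=bolting_date)
    done = accumulate_to_threshold(
        hourly, _dt.datetime.combine(bolting_date, _dt.time()), params
    )
    return None if done is None else done.date()


def predict_bolting(
    germination_date: _dt.date,
    climate: ClimateSeries,
    config: BoltingModelConfig,
) -> _dt.date | None:
    """Bolting date for a germination date under the configured model."""
    if config.model == "fixed":
        return germination_date + _dt.timedelta(days=config.duration_days)
    # generic (photo)thermal accumulator, optional vernalization scaling
    assert config.params is not None
    if config.params.threshold <= 0:  # unreachable (validated), kept for clarity
        return germination_date
    hourly = hourly_series(climate, start=germination_date)
    mult = None
    if config.vernalization_table is not None:
        knots = np.asarray(config.vernalization_table, dtype=float)
        cold_hours = np.cumsum(hourly["temp"].to_numpy() < config.cold_threshold)
        mult = np.interp(cold_hours, knots[:, 0], knots[:, 1])
    done = accumulate_to_threshold(
        hourly, _dt.datetime.combine(germination_date, _dt.time()), config.params,
        multiplier=mult,
    )
    return None if done is None else done.date()


def constant_temperature_days(
    temperature: float, params: ThermalModelParams, photoperiod: float = 16.0
) -> float:
    """Closed-form days to completion at constant temperature.

    threshold / (24 (T - T_b)) for the thermal model; the photothermal
    model only accrues during the ``photoperiod`` daylight hours.
    """
    if temperature <= params.t_b:
        return np.inf
    hours_per_day = photoperiod if params.mode == "photothermal" else 24.0
    return params.threshold / (hours_per_day * (temperature - params.t_b))


@dataclass(frozen=True)
class SeedSetFit:
    params: ThermalModelParams
    r_squared: float
    sse: float
    n_obs: int


def _predicted_days(obs: SeedSetObservation, params: ThermalModelParams) -> float:
    if obs.temperature is not None:
        return constant_temperature_days(obs.temperature, params, obs.photoperiod)
    date = predict_seed_set(obs.bolting_date, obs.climate, params)
    if date is None:
        return np.inf
    return (date - obs.bolting_date).days


def fit_seed_set_params(
    observations: Sequence[SeedSetObservation],
    mode: Literal["thermal", "photothermal"] = "thermal",
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 15.0), (100.0, 50000.0)),
) -> SeedSetFit:
    """Least-squares fit of (T_b, threshold) to bolting-to-seed-set durations.

    Minimises squared error in predicted days across observations and
    reports R^2 = 1 - SSE/SST.  Requires at least three distinct
    temperature regimes (two parameters plus a check on curvature); the
    optimiser multi-starts from a coarse T_b grid with the threshold
    initialised from the closed form at each start.
    """
    if len(observations) < 3:
        raise PhenologyError("need >= 3 observations to fit (T_b, threshold)")
    temps = {o.temperature for o in observations if o.temperature is not None}
    if len(temps) < 3 and not any(o.climate is not None for o in observations):
        raise PhenologyError("need >= 3 distinct temperature regimes")

    days = np.array([o.days for o in observations], dtype=float)
    (tb_lo, tb_hi), (th_lo, th_hi) = bounds
    big = 10.0 * days.max()

    def resid(p):
        params = ThermalModelParams(t_b=p[0], threshold=p[1], mode=mode)
        pred = np.array([_predicted_days(o, params) for o in observations])
        return np.where(np.isfinite(pred), pred, big) - days

    ref = next(o for o in observations if o.temperature is not None)
    hpd = ref.photoperiod if mode == "photothermal" else 24.0
    best = None
    for tb0 in np.linspace(tb_lo, min(tb_hi, ref.temperature - 0.5), 6):
        th0 = np.clip(ref.days * hpd * (ref.temperature - tb0), th_lo, th_hi)
        sol = least_squares(
            resid, [tb0, th0], bounds=([tb_lo, th_lo], [tb_hi, th_hi]),
            xtol=1e-12, ftol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    sse = 2.0 * best.cost
    sst = float(np.sum((days - days.mean()) ** 2))
    return SeedSetFit(
        params=ThermalModelParams(t_b=float(best.x[0]), threshold=float(best.x[1]), mode=mode),
        r_squared=np.nan if sst == 0 else 1.0 - sse / sst,
        sse=float(sse),
        n_obs=len(observations),
    )
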