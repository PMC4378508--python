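"""Synthetic inputs for every pipeline stage.

No field or laboratory measurements ship with this package, so tests and
worked examples run on generated data: sinusoidal multi-year daily
temperature series with AR(1) day-to-day persistence, germination assay
time-series drawn binomially from the dormancy model, and constant-regime
seed-set observations from the thermal-time closed form.  Every generator
is deterministic under a fixed seed, and each noise-free mode is an exact
fixed point of the corresponding fitting routine.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from seedlife.climate import ClimateSeries, DailyClimateRecord
from seedlife.germination import GerminationAssay, GerminationParams, germination_probability
from seedlife.phenology import SeedSetObservation

__all__ = [
    "SyntheticClimateSpec",
    "SyntheticAssaySpec",
    "synth_climate",
    "synth_germination_assays",
    "synth_seed_set_obs",
]

#: Incubation sampling days of the growth-chamber assay design (a fresh
#: un-stratified plate at day 0, then 3-42 d of dark incubation).
ASSAY_DAYS = (0.0, 3.0, 7.0, 14.0, 21.0, 28.0, 42.0)
#: Maturation temperatures of the training design (degC).
ASSAY_T_M = (12.0, 13.0, 14.0, 15.0, 17.0, 18.0)
#: Dark-incubation (imbibition) temperatures (degC).
ASSAY_T_I = (4.0, 8.0, 12.0, 15.0, 20.0)


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Parameters of a sinusoidal synthetic climate.

    Daily mean temperature follows
    ``mean + amplitude * cos(2*pi*(doy - peak_doy)/365)`` plus AR(1) noise
    with stationary sd ``noise_sd`` and coefficient ``ar_coeff`` (week-scale
    persistence, so trailing 7-day maturation windows see realistic runs of
    warm/cold days).  ``t_min``/``t_max`` sit symmetrically ``diurnal_range``
    apart around the mean.
    """

    mean: float = 9.0
    amplitude: float = 8.0
    diurnal_range: float = 6.0
    noise_sd: float = 0.0
    ar_coeff: float = 0.6
    latitude: float = 52.0
    longitude: float = 15.0
    n_years: int = 1
    peak_doy: int = 200
    start: _dt.date = _dt.date(2001, 1, 1)
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.diurnal_range < 0 or self.noise_sd < 0:
            raise ValueError("amplitude, diurnal range and noise sd must be >= 0")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")


def synth_climate(spec: SyntheticClimateSpec) -> ClimateSeries:
    """Generate a daily climate series from a :class:`SyntheticClimateSpec`."""
    n_days = sum(
        366 if _is_leap(spec.start.year + k) else 365 for k in range(spec.n_years)
    )
    dates = [spec.start + _dt.timedelta(days=i) for i in range(n_days)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    seasonal = spec.mean + spec.amplitude * np.cos(2 * np.pi * (doy - spec.peak_doy) / 365.0)
    noise = np.zeros(n_days)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar_coeff**2)
        eps = rng.normal(0.0, innov_sd, n_days)
        noise[0] = rng.normal(0.0, spec.noise_sd)
        for i in range(1, n_days):
            noise[i] = spec.ar_coeff * noise[i - 1] + eps[i]
    t_mean = seasonal + noise
    half = spec.diurnal_range / 2.0
    recs = [
        DailyClimateRecord(date=d, t_min=tm - half, t_mean=tm, t_max=tm + half)
        for d, tm in zip(dates, t_mean)
    ]
    return ClimateSeries(
        recs, latitude=spec.latitude, longitude=spec.longitude, label=spec.label
    )


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


@dataclass(frozen=True)
class SyntheticAssaySpec:
    """Design of a synthetic germination experiment.

    Defaults mirror the growth-chamber protocol: batches of 50 seeds
    (25-50 in the protocol), five replicate batches per treatment, sampled
    at 0/3/7/14/21/28/42 days of dark incubation, over the training grid of
    maturation and imbibition temperatures.
    """

    params: GerminationParams
    t_m_levels: tuple[float, ...] = ASSAY_T_M
    t_i_levels: tuple[float, ...] = ASSAY_T_I
    days: tuple[float, ...] = ASSAY_DAYS
    n_seeds: int = 50
    replicates: int = 5
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("need at least one seed per batch")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def synth_germination_assays(spec: SyntheticAssaySpec) -> list[GerminationAssay]:
    """Draw germination time-series from the dormancy model.

    With noise, germinated counts are Binomial(n_seeds, P(G)) per plate;
    noise-free mode returns the exact model fractions (total = 1), which
    downstream fits recover exactly.
    """
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.days, dtype=float)
    out: list[GerminationAssay] = []
    for t_m in spec.t_m_levels:
        for t_i in spec.t_i_levels:
            p = germination_probability(days, t_m, t_i, spec.params)
            n_reps = spec.replicates if spec.noise else 1
            for rep in range(n_reps):
                if spec.noise:
                    germ = rng.binomial(spec.n_seeds, p).astype(float)
                    total = np.full_like(days, float(spec.n_seeds))
                else:
                    germ, total = p.copy(), np.ones_like(days)
                out.append(
                    GerminationAssay(
                        t_m=t_m, t_i=t_i, times=days, germinated=germ,
                        total=total, replicate=rep,
                    )
                )
    return out


def synth_seed_set_obs(
    t_b: float,
    threshold: float,
    temperatures: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
    photoperiod: float = 16.0,
) -> list[SeedSetObservation]:
    """Constant-regime bolting-to-seed-set durations from the closed form.

    days = threshold / (24 (T - t_b)) plus optional Gaussian noise.
    Temperatures at or below the base temperature never complete and are
    rejected.
    """
    for T in temperatures:
        if T <= t_b:
            raise ValueError(f"temperature {T} degC at/below base temperature {t_b}")
    rng = np.random.default_rng(seed)
    obs = []
    for T in temperatures:
        exact = threshold / (24.0 * (T - t_b))
        for _ in range(replicates):
            days = exact + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            obs.append(
                SeedSetObservation(
                    days=max(days, 0.1), temperature=T, photoperiod=photoperiod
                )
            )
    return obs
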