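"""Probabilistic model of seed dormancy and germination.

A seed population is described by two independent dormancy states: primary
dormancy, set on the mother plant during seed maturation, and secondary
dormancy, induced de novo after imbibition.  A random seed germinates iff
it is in neither state:

    P(G) = 1 - P(D),        P(D) = P(Dp) + P(Ds) - P(Dp) P(Ds)

Both state probabilities follow cumulative logistic curves in imbibition
time ``x`` (days):

    P(Dp)(x) = 1 / (1 + exp(Rp (x + Ap)))
    P(Ds)(x) = 1 - 1 / (1 + exp(Rs (x + As)))

where ``Rp`` is the primary-dormancy loss rate and ``Rs`` the
secondary-dormancy induction rate.  The offsets ``Ap = -ln(99)/Rp`` and
``As = -ln(99)/Rs`` reposition the curves so that at ``x = 0`` a fresh
population is almost fully primary-dormant, P(Dp)(0) = 0.99, and has
essentially no secondary dormancy, P(Ds)(0) = 0.01.

The temperature dependence carries the biology: primary dormancy loss is
linear in seed-maturation temperature ``T_m`` and secondary dormancy
induction is exponential in imbibition temperature ``T_i``:

    Rp = a T_m + b,         Rs = c exp(d T_i)

with only four free parameters (a, b, c, d).  ``Rp`` changes sign at
``T_m = -b/a`` (about 14 degC with the default parameters): seeds matured
below this temperature never lose primary dormancy, seeds matured above it
pass through a transient low-dormancy window before secondary dormancy
closes it — the switch that divides progeny into seed-bank entrants and
immediate germinators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import expit

__all__ = [
    "GerminationParams",
    "DormancyState",
    "RateAndOffsets",
    "GerminationAssay",
    "GerminationFit",
    "RateModelSpec",
    "TmEstimate",
    "LN99",
    "primary_rate",
    "secondary_rate",
    "offsets",
    "primary_dormancy",
    "secondary_dormancy",
    "germination_probability",
    "dormancy_probabilities",
    "fit_germination_params",
    "select_rate_model",
    "infer_maturation_temperature",
]

#: ln(99): the logit of the x=0 anchors (0.99 for P(Dp), 0.01 for P(Ds)).
LN99 = float(np.log(99.0))


class GerminationModelError(ValueError):
    """Invalid parameters or an unidentifiable fitting design."""


@dataclass(frozen=True)
class GerminationParams:
    """The four constants of the dormancy model.

    a, b : slope (per day per degC) and intercept (per day) of the
        primary-dormancy loss rate ``Rp = a*T_m + b``.
    c, d : pre-exponential (per day) and exponential coefficient (per degC)
        of the secondary-dormancy induction rate ``Rs = c*exp(d*T_i)``.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise GerminationModelError("a must be > 0 (dormancy loss speeds up with T_m)")
        if self.c <= 0 or self.d <= 0:
            raise GerminationModelError("c and d must be > 0 (Rs positive, increasing in T_i)")

    @property
    def switch_temperature(self) -> float:
        """Maturation temperature at which Rp crosses zero (-b/a)."""
        return -self.b / self.a


@dataclass(frozen=True)
class RateAndOffsets:
    """Rates and the offsets that anchor the logistic curves at x = 0."""

    r_p: float
    r_s: float
    a_p: float | None  # None encodes the Rp = 0 limit (P(Dp) constant at 0.99)
    a_s: float


@dataclass(frozen=True)
class DormancyState:
    """Population dormancy state at one imbibition time."""

    x: float
    p_primary: float
    p_secondary: float
    p_dormant: float
    p_germ: float


@dataclass
class GerminationAssay:
    """One observed germination time-series.

    ``germinated``/``total`` counts are assumed to already exclude seeds
    that germinated during the dark incubation (removed from numerator and
    denominator alike, as in the assay protocol).
    """

    t_m: float
    t_i: float
    times: np.ndarray
    germinated: np.ndarray
    total: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.germinated = np.asarray(self.germinated, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if not (len(self.times) == len(self.germinated) == len(self.total)):
            raise GerminationModelError("times/germinated/total length mismatch")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise GerminationModelError("incubation times must be non-negative and increasing")
        if np.any(self.germinated < 0) or np.any(self.germinated > self.total):
            raise GerminationModelError("require 0 <= germinated <= total")

    @property
    def fraction(self) -> np.ndarray:
        return self.germinated / self.total


def primary_rate(t_m: float | np.ndarray, params: GerminationParams):
    """Primary-dormancy loss rate Rp = a*T_m + b (may be negative)."""
    return params.a * np.asarray(t_m, dtype=float) + params.b


def secondary_rate(t_i: float | np.ndarray, params: GerminationParams):
    """Secondary-dormancy induction rate Rs = c*exp(d*T_i) (always > 0)."""
    return params.c * np.exp(params.d * np.asarray(t_i, dtype=float))


def offsets(r_p: float, r_s: float) -> RateAndOffsets:
    """Offsets repositioning the curves onto their x = 0 anchors.

    Substituting x = 0 with P(Dp) = 0.99 into the primary logistic gives
    exp(Rp*Ap) = 1/99, i.e. Ap = -ln(99)/Rp; the same substitution with
    P(Ds) = 0.01 gives As = -ln(99)/Rs.  Both hold for negative Rp too
    (the anchor only fixes the product Rp*Ap).  Rp = 0 has no finite
    offset; the continuous limit P(Dp) = 0.99 for all x is used instead.
    """
    if r_s <= 0:
        raise GerminationModelError(f"secondary rate must be positive, got {r_s}")
    a_p = None if r_p == 0 else -LN99 / r_p
    return RateAndOffsets(r_p=r_p, r_s=r_s, a_p=a_p, a_s=-LN99 / r_s)


def primary_dormancy(x, r_p):
    """P(Dp)(x) under the anchored offset; continuous in Rp through 0.

    With Ap = -ln(99)/Rp the exponent Rp*(x + Ap) collapses to
    Rp*x - ln(99), so P(Dp) = sigmoid(ln(99) - Rp*x): well defined and
    equal to 0.99 at x = 0 for every Rp, including the Rp -> 0 limit.
    """
    return expit(LN99 - np.asarray(r_p) * np.asarray(x, dtype=float))


def secondary_dormancy(x, r_s):
    """P(Ds)(x) under the anchored offset: sigmoid(Rs*x - ln(99))."""
    return expit(np.asarray(r_s) * np.asarray(x, dtype=float) - LN99)


def germination_probability(x, t_m, t_i, params: GerminationParams):
    """P(G) = (1 - P(Dp)) (1 - P(Ds)), vectorised over any argument."""
    p_p = primary_dormancy(x, primary_rate(t_m, params))
    p_s = secondary_dormancy(x, secondary_rate(t_i, params))
    return (1.0 - p_p) * (1.0 - p_s)


def dormancy_probabilities(
    x: float, t_m: float, t_i: float, params: GerminationParams
) -> DormancyState:
    """Full dormancy state of a population at imbibition time ``x`` days."""
    if x < 0:
        raise GerminationModelError("imbibition time must be >= 0")
    p_p = float(primary_dormancy(x, primary_rate(t_m, params)))
    p_s = float(secondary_dormancy(x, secondary_rate(t_i, params)))
    p_d = p_p + p_s - p_p * p_s
    return DormancyState(x=x, p_primary=p_p, p_secondary=p_s, p_dormant=p_d, p_germ=1.0 - p_d)


# ---------------------------------------------------------------------------
# fitting


def _pool_points(assays: Sequence[GerminationAssay]):
    tm = np.concatenate([np.full(len(a.times), a.t_m) for a in assays])
    ti = np.concatenate([np.full(len(a.times), a.t_i) for a in assays])
    x = np.concatenate([a.times for a in assays])
    frac = np.concatenate([a.fraction for a in assays])
    return tm, ti, x, frac


def _check_design(assays: Sequence[GerminationAssay]) -> None:
    if len({a.t_m for a in assays}) < 3 or len({a.t_i for a in assays}) < 3:
        raise GerminationModelError(
            "fitting needs assays spanning >= 3 maturation and >= 3 imbibition temperatures"
        )


def _pooled_r2(frac: np.ndarray, pred: np.ndarray) -> float:
    sse = float(np.sum((frac - pred) ** 2))
    sst = float(np.sum((frac - frac.mean()) ** 2))
    return np.nan if sst == 0 else 1.0 - sse / sst


@dataclass(frozen=True)
class GerminationFit:
    """Result of fitting the four-parameter model to pooled assay data."""

    params: GerminationParams
    r_squared: float
    sse: float
    n_points: int
    converged: bool


# deterministic multi-start grid: signs/scales bracketing the plausible range
_STARTS = [
    (a0, b0, c0, d0)
    for a0 in (0.5, 2.0)
    for b0 in (-30.0, -5.0)
    for c0 in (0.01, 0.1)
    for d0 in (0.1, 0.4)
]
_BOUNDS = ([1e-4, -200.0, 1e-6, 1e-4], [50.0, 50.0, 20.0, 2.0])


def fit_germination_params(
    assays: Sequence[GerminationAssay], seed: int = 0
) -> GerminationFit:
    """Least-squares fit of (a, b, c, d) to pooled germination fractions.

    All replicate points enter unweighted; the objective is
    sum((observed fraction - P(G))^2) over every (T_m, T_i, x) point, and
    R^2 is pooled over the same points.  A fixed grid of start points
    guards against the local minima of the exponential secondary rate;
    ``seed`` is accepted for interface symmetry but the optimisation is
    fully deterministic.
    """
    _check_design(assays)
    tm, ti, x, frac = _pool_points(assays)

    def resid(p):
        a, b, c, d = p
        pred = (1.0 - primary_dormancy(x, a * tm + b)) * (
            1.0 - secondary_dormancy(x, c * np.exp(d * ti))
        )
        return pred - frac

    best = None
    for start in _STARTS:
        try:
            sol = least_squares(resid, start, bounds=_BOUNDS, xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        sse = 2.0 * sol.cost
        if best is None or sse < best[0] - 1e-14:
            best = (sse, sol)
    if best is None:
        raise GerminationModelError("germination fit failed to converge from every start")
    sse, sol = best
    a, b, c, d = sol.x
    pred = frac + resid(sol.x)
    return GerminationFit(
        params=GerminationParams(a=float(a), b=float(b), c=float(c), d=float(d)),
        r_squared=_pooled_r2(frac, pred),
        sse=float(sse),
        n_points=len(frac),
        converged=bool(sol.success),
    )


# ---------------------------------------------------------------------------
# nine-way rate-model selection

RateForm = Literal["linear", "exponential", "logistic"]

_FORM_NPARAMS = {"linear": 2, "exponential": 2, "logistic": 3}


def _rate_fn(form: RateForm) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    if form == "linear":
        return lambda T, p: p[0] * T + p[1]
    if form == "exponential":
        return lambda T, p: p[0] * np.exp(p[1] * T)
    if form == "logistic":
        return lambda T, p: p[0] * expit(p[1] * (T - p[2]))
    raise GerminationModelError(f"unknown rate form {form!r}")


def _form_starts(form: RateForm, primary: bool) -> list[list[float]]:
    if form == "linear":
        return [[1.0, -15.0], [0.5, -5.0]] if primary else [[0.05, 0.1], [0.02, 0.5]]
    if form == "exponential":
        return [[0.05, 0.2], [0.5, 0.05]]
    return [[2.0, 0.5, 14.0], [1.0, 1.0, 10.0]]


def _form_bounds(form: RateForm) -> tuple[list[float], list[float]]:
    if form == "linear":
        return ([-50.0, -200.0], [50.0, 200.0])
    if form == "exponential":
        return ([1e-6, 1e-4], [50.0, 2.0])
    return ([1e-6, 1e-3, -20.0], [50.0, 10.0, 60.0])


@dataclass(frozen=True)
class RateModelSpec:
    """One cell of the 3 x 3 rate-model comparison grid."""

    primary_form: RateForm
    secondary_form: RateForm
    n_params: int
    r_squared: float
    rates: tuple[float, ...] = field(default=(), compare=False)


def select_rate_model(assays: Sequence[GerminationAssay]) -> list[RateModelSpec]:
    """Fit all nine (primary x secondary) rate-form combinations.

    Each combination models Rp as a function of T_m and Rs as a function of
    T_i, with linear and exponential forms carrying 2 parameters and the
    logistic form 3.  Results are ranked by pooled R^2, ties broken by
    fewer parameters.  With degenerate data (zero variance in the observed
    fractions) R^2 is undefined and reported as NaN, ranked last.
    """
    _check_design(assays)
    tm, ti, x, frac = _pool_points(assays)
    out = []
    for pform in ("linear", "exponential", "logistic"):
        for sform in ("linear", "exponential", "logistic"):
            rp_fn, rs_fn = _rate_fn(pform), _rate_fn(sform)
            n_p = _FORM_NPARAMS[pform]

            def resid(theta):
                rp = rp_fn(tm, theta[:n_p])
                rs = rs_fn(ti, theta[n_p:])
                pred = (1.0 - primary_dormancy(x, rp)) * (1.0 - secondary_dormancy(x, rs))
                return pred - frac

            lo_p, hi_p = _form_bounds(pform)
            lo_s, hi_s = _form_bounds(sform)
            best = None
            for sp in _form_starts(pform, primary=True):
                for ss in _form_starts(sform, primary=False):
                    try:
                        sol = least_squares(
                            resid, sp + ss, bounds=(lo_p + lo_s, hi_p + hi_s),
                            xtol=1e-10, ftol=1e-10,
                        )
                    except Exception:
                        continue
                    if best is None or sol.cost < best.cost:
                        best = sol
            if best is None:
                r2, theta = np.nan, ()
            else:
                r2 = _pooled_r2(frac, frac + resid(best.x))
                theta = tuple(float(v) for v in best.x)
            out.append(
                RateModelSpec(
                    primary_form=pform,
                    secondary_form=sform,
                    n_params=n_p + _FORM_NPARAMS[sform],
                    r_squared=r2,
                    rates=theta,
                )
            )
    return sorted(
        out,
        key=lambda s: (-(s.r_squared if np.isfinite(s.r_squared) else -np.inf), s.n_params),
    )


# ---------------------------------------------------------------------------
# inverse inference of maturation temperature


@dataclass(frozen=True)
class TmEstimate:
    """Maturation-temperature estimate for a seed lot of unknown origin."""

    t_m: float
    sse: float
    flat_objective: bool
    interval: tuple[float, float]


def infer_maturation_temperature(
    assays: Sequence[GerminationAssay],
    params: GerminationParams,
    bounds: tuple[float, float] = (5.0, 25.0),
) -> TmEstimate:
    """Infer T_m of one seed lot from germination series at known T_i.

    With (a, b, c, d) fixed, the only unknown is the lot's maturation
    temperature; it is estimated by 1-D bounded least squares on the pooled
    fractions.  In the deep-dormancy regime (Rp < 0) the predicted
    germination is near zero regardless of how negative Rp is, so
    all-dormant lots leave the objective flat below the switch temperature:
    the near-optimal interval is reported and ``flat_objective`` flags
    spans wider than 2 degC.
    """
    if not assays:
        raise GerminationModelError("need at least one assay series")
    ti = np.concatenate([np.full(len(a.times), a.t_i) for a in assays])
    x = np.concatenate([a.times for a in assays])
    frac = np.concatenate([a.fraction for a in assays])
    rs = secondary_rate(ti, params)
    p_s = secondary_dormancy(x, rs)

    def sse(t_m: float) -> float:
        pred = (1.0 - primary_dormancy(x, params.a * t_m + params.b)) * (1.0 - p_s)
        return float(np.sum((pred - frac) ** 2))

    grid = np.linspace(bounds[0], bounds[1], 201)
    vals = np.array([sse(t) for t in grid])
    t0 = grid[int(np.argmin(vals))]
    lo = max(bounds[0], t0 - 0.5)
    hi = min(bounds[1], t0 + 0.5)
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    best_sse = min(float(res.fun), float(vals.min()))
    best_tm = float(res.x) if res.fun <= vals.min() else float(t0)
    # flatness is judged on the grid: the span of grid points statistically
    # indistinguishable from the grid optimum
    grid_min = float(vals.min())
    near = grid[vals <= grid_min + 1e-6 * (1.0 + grid_min)]
    interval = (float(near.min()), float(near.max()))
    flat = (interval[1] - interval[0]) > 2.0
    if flat:
        warnings.warn(
            f"flat T_m objective: near-optimal interval {interval[0]:.1f}-"
            f"{interval[1]:.1f} degC (all-dormant lot?)",
            stacklevel=2,
        )
    return TmEstimate(t_m=best_tm, sse=best_sse, flat_objective=flat, interval=interval)
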