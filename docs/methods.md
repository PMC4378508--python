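# Methods

`seedlife` models the full annual life cycle of *Arabidopsis thaliana*
Col-0 as three coupled sub-models — climate, phenology, seed dormancy —
plus a simulator that chains them and a synthetic-data module that
generates every input the pipeline needs. This note records the models,
their assumptions, the defaults, and the choices made where the design was
genuinely open.

## Climate driver

All development is driven by daily minimum / mean / maximum air
temperature. Photothermal accumulation needs hourly resolution, so each
day is expanded with a fixed rule: hours starting 21:00–01:00 take the
daily minimum, hours starting 09:00–13:00 take the daily maximum, and the
remaining 14 hours take the daily mean. The hour windows are half-open so
the day partitions exactly (5 + 5 + 14 = 24). Two consequences worth
knowing: the hourly mean equals the daily mean only when the daily extremes
are symmetric about it, and the diurnal phase is in civil clock time (the
≤ 1 h phase ambiguity is immaterial for daily thermal sums).

Sunrise and sunset come from the standard sunrise equation
(declination −23.44°·cos(2π(N+10)/365), hour angle clamped for polar
day/night), symmetric about 12:00 local. Accuracy is within ~10 minutes of
a 1-minute solar-elevation scan for |lat| ≤ 60°, far finer than the binary
per-hour daylight flag requires.

Multi-year series are reduced to a 365-day climatology by averaging each
day of year across years (Feb 29 folded into Feb 28); simulations recycle
the climatology cyclically over a two-year horizon past sowing. Sowings
whose accumulators have not reached threshold by then report
`did_not_complete` — the realistic far-north outcome, not an error.

## Phenology: thermal time to first seed set

Development from bolting to first seed set accumulates thermal time
θ(t) = max(T(t) − T_b, 0) °C·h per hour and completes at a fixed threshold
T_h. Packaged defaults are the published Col-0 values **T_b = 5.25 °C,
T_h = 5370 °C·h**. At constant T > T_b this collapses to
days = T_h / (24 (T − T_b)), used both for fitting constant-regime
laboratory observations and as an independent check on the accumulator
(agreement within the 1 h quantization; no sub-hour interpolation, since
input is hour-quantized anyway).

A photothermal variant gates the hourly increment by a binary daylight
indicator. "Daylight" at hour resolution admits no finer reading without
inventing data; the variant is retained because the thermal-vs-photothermal
comparison is part of the analysis, even though the thermal model is the
better seed-set predictor.

Fitting uses bounded least squares (T_b ∈ [0, 15] °C,
T_h ∈ [100, 50000] °C·h) multi-started from a coarse T_b grid with the
threshold initialised from the closed form; the objective is squared error
in predicted days and R² = 1 − SSE/SST. At least three distinct
temperature regimes are required (two parameters plus curvature).

Germination → bolting is a pluggable interface: a fixed-duration stub (for
tests and decoupled experiments) and a generic (photo)thermal accumulator
with an optional vernalization hook — a piecewise-linear multiplier in
[0, 1] applied to each hourly increment as a function of accumulated cold
hours. Published genotype-specific bolting parameterizations are consumed
as external configuration only. Simulations in this repository use a
documented **surrogate**: photothermal accumulation above 3 °C to a
threshold of 6500 °C·h, chosen so that an October sowing at the reference
climate (below) bolts in mid-April — winter-annual phenology. It is not a
published parameter set and supports only qualitative conclusions.

## Germination: primary and secondary dormancy

A seed germinates iff it is in neither dormancy state; with independent
states, P(G) = 1 − [P(Dp) + P(Ds) − P(Dp)P(Ds)] = (1 − P(Dp))(1 − P(Ds)).
Both states follow cumulative logistic curves in imbibition time x (days):

    P(Dp)(x) = 1 / (1 + exp(Rp (x + Ap)))       primary, lost at rate Rp
    P(Ds)(x) = 1 − 1 / (1 + exp(Rs (x + As)))   secondary, gained at rate Rs

The offsets anchor the fresh-seed state: Ap = −ln(99)/Rp puts
P(Dp)(0) = 0.99 and As = −ln(99)/Rs puts P(Ds)(0) = 0.01 (the only
biologically coherent assignment: populations start primary-dormant and
acquire secondary dormancy later). Substituting the offsets collapses the
exponents to Rp·x − ln 99, so the implementation evaluates
σ(ln 99 − Rp·x) — exact at x = 0 for any rate, continuous through Rp = 0
(the Rp → 0 limit is the constant 0.99), and valid for negative Rp, where
primary dormancy *deepens* with time.

Temperature enters through the rates, with four free constants:

    Rp = a·T_m + b   (linear in seed-maturation temperature)
    Rs = c·e^{d·T_i} (exponential in imbibition temperature)

Defaults are the published **a = 1.56, b = −21.79 d⁻¹·°C⁻¹/d⁻¹ and
c = 0.05 d⁻¹, d = 0.18 °C⁻¹**. The zero of Rp at −b/a ≈ 13.97 °C is the
emergent dormancy switch: seeds matured below ~14 °C never lose primary
dormancy (seed-bank entrants); above it they pass through a transient
germinable window before secondary dormancy — induced faster the warmer
the imbibition environment — closes it.

Fitting pools every (T_m, T_i, x) observation unweighted (replicate points
enter individually) and minimises Σ(fraction − P(G))² with bounded least
squares from a fixed 16-point start grid; R² is pooled over all points.
Observed fractions are assumed to already exclude seeds that germinated in
darkness (removed from numerator and denominator, as in the assay
protocol). The nine-way model comparison crosses {linear, exponential,
logistic} forms for Rp(T_m) × Rs(T_i); linear and exponential carry 2
parameters, logistic (L·σ(k(T − T₀))) carries 3, giving totals 4–6.
Ranking is by pooled R², ties to fewer parameters; degenerate data with
zero variance report R² = NaN rather than crashing.

Inverse inference of a lot's maturation temperature holds (a, b, c, d)
fixed and minimises the same SSE over T_m alone (bounded, default
5–25 °C; grid scan plus local refinement, hence invariant to duplicated
rows). Identifiability is asymmetric: below the switch all predictions are
"near-zero germination", so all-dormant lots leave the objective flat
across the whole sub-switch range; well above the switch (≳ 17 °C) primary
dormancy vanishes within days for *any* such T_m, so the objective also
saturates from above. Both regimes are flagged by a wide-interval warning
(near-optimal grid span > 2 °C); point recovery on noise-free data is
exact in all regimes.

## Simulator

For each germination date: bolting → first seed set → T_m = mean daily
temperature over the trailing 7 days ending at seed set (the final days
before harvest dominate dormancy depth) → progeny germination evaluated at
x = H days after shedding with T_i = mean daily temperature over
[shedding, shedding + H). Default **H = 28 d**, the longest common
incubation of the assay design. The construction of the published progeny
heat maps (imbibition window, evaluation time, light assumption) is not
stated; both H and the T_i window are configurable, and no attempt is made
to match figures pixel-wise. The choice matters: with warm post-shedding
weather, secondary dormancy closes the window by day 28, so H = 28
measures the *eventual* dormancy state while short horizons (e.g. H = 7)
capture the transient immediately-germinable window. The genotype cohort
analysis therefore reports both.

Cohort summaries assume seed set lasts 30 days from first seed set with
shedding weighted either uniformly or (default) as a truncated normal
(mean day 15, sd 7 d); each shedding date gets its own trailing-week T_m
and post-shedding T_i. `fraction_low_dormant` is the shedding-weighted
mean germination probability (continuous); a hard-cutoff mode
(P(G) > 0.5 per shedding date) is available for bar-style summaries.
Warming scenarios shift the whole climate by a constant and re-run a fixed
autumn sowing.

## Synthetic data

The generator is the stated world of all tests:

* **Climate** — daily mean = annual mean + amplitude·cos(2π(doy − 200)/365)
  + AR(1) noise (coefficient 0.6, stationary sd as configured); t_min/t_max
  sit symmetrically `diurnal_range` apart. AR(1) rather than white noise so
  trailing 7-day maturation windows see realistic warm/cold runs. The
  reference climate is mean 9 °C, amplitude 8 °C, diurnal range 6 °C —
  a central-European temperate profile. Not emulated: weather fronts,
  skewed diurnal cycles, humidity/precipitation, microclimate.
* **Assays** — germinated ~ Binomial(50, P(G)) per plate, 5 replicate
  batches, times 0/3/7/14/21/28/42 d, T_m ∈ {12, 13, 14, 15, 17, 18} °C,
  T_i ∈ {4, 8, 12, 15, 20} °C (the training design); noise-free mode
  returns exact model fractions.
* **Seed set** — days from the constant-temperature closed form plus
  Gaussian noise (sd 0.5 d in the drivers, matching few-day replicate
  scatter).

A green recovery test therefore establishes that the fitting machinery
inverts the model on data *generated by the model* at the stated design —
not that the model is correct for real seeds, and not that published R²
values (computed on figure-only laboratory data) are reproduced.

## Numerical choices and limitations

* Logistics evaluated via `scipy.special.expit` on the collapsed exponent —
  no overflow at extreme rates/times; probabilities exact in [0, 1].
* Completion is the first hour whose cumulative sum ≥ threshold
  (`searchsorted`); ±1 h discretization against closed forms.
* Optimisation: `scipy.optimize.least_squares` (bounded trust region) with
  deterministic multi-start grids everywhere; `minimize_scalar` (bounded)
  for the 1-D T_m inversion; tolerances 1e-10–1e-12. All generators take
  explicit integer seeds; nothing draws from global RNG state.
* The climatology is a point estimate; inter-annual variance is not
  propagated. No water availability, light quality, after-ripening, or
  seed-bank demography. Real-location climate CSVs are accepted but never
  required, and no claims are made about real sites.
* Under the default H = 28 construction, a severely delayed genotype sheds
  into such warm weather that fast secondary dormancy induction can
  *reduce* its low-dormant fraction relative to a mild delay — the
  direction of the genotype effect depends on the unspecified heat-map
  construction, which is why both horizons are reported rather than
  adjudicated.
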