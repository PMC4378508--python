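# seedlife

Full life-cycle modelling of *Arabidopsis thaliana* Col-0: a thermal-time
model of development from bolting to first seed set, a probabilistic model
of primary and secondary seed dormancy driven by seed-maturation and
imbibition temperatures, and a climate-driven simulator that couples them
into whole life histories — flowering and seed-set dates for any
germination date, maturation temperatures at shedding, progeny germination
maps, flowering-delay genotype cohorts, and warming scenarios.

The package is aimed at plant phenology and life-history modellers. Its
central object of study is an *external coincidence*: winter-annual
cohorts set seed just as the ambient temperature crosses a ~14 °C switch
in seed dormancy state, so a single genotype splits its progeny into
dormant seed-bank entrants and immediate germinators (bet hedging), and
this alignment is buffered against large differences in climate.

## The models

**Seed set (thermal time).** Each hour with temperature T above a base
T_b contributes θ = T − T_b °C·h; the phase from bolting to first seed set
completes at a fixed threshold T_h:

    T_h = Σ_t θ(t),   θ(t) = max(T(t) − T_b, 0)

Defaults: T_b = 5.25 °C, T_h = 5370 °C·h. At constant temperature,
days = T_h / (24 (T − T_b)). A daylight-gated photothermal variant is
included for comparison.

**Dormancy / germination.** A seed germinates iff it is neither
primary- nor secondary-dormant, P(G) = (1 − P(Dp))(1 − P(Ds)), with
logistic kinetics in imbibition time x (days):

    P(Dp)(x) = 1/(1 + e^{Rp(x + Ap)}),  P(Ds)(x) = 1 − 1/(1 + e^{Rs(x + As)})
    Rp = a·T_m + b,   Rs = c·e^{d·T_i}

Offsets Ap = −ln(99)/Rp, As = −ln(99)/Rs anchor fresh seed at
P(Dp)(0) = 0.99, P(Ds)(0) = 0.01. Defaults a = 1.56, b = −21.79, c = 0.05,
d = 0.18 put the zero of Rp — the dormancy switch — at
−b/a ≈ 13.97 °C: seeds matured below it stay dormant; above it, a
transient germinable window opens before secondary dormancy (faster when
imbibed warm) closes it.

**Climate.** Daily min/mean/max series, expanded hourly (min over
21:00–02:00, max over 09:00–14:00, mean elsewhere), day length from the
standard sunrise equation, multi-year climatologies recycled cyclically.

## Worked example

No laboratory data ship with the package; the synthetic module generates
assay and climate inputs from the model itself. Fitting the
four-parameter dormancy model to binomially-noisy assays over the
training design (6 maturation × 5 imbibition temperatures, 7 time points,
5 replicates of 50 seeds):

```
$ python analysis/01_synthesize_inputs.py
$ python analysis/02_fit_germination_model.py
exact: a=1.560 b=-21.790 c=0.0500 d=0.1800 R2=1.0000
binomial_n50_5rep: a=1.592 b=-22.242 c=0.0490 d=0.1820 R2=0.9940
best rate model: linear/exponential (4 params, R2=0.9940)
```

The noise-free fit recovers the generating constants exactly; binomial
sampling noise moves them by ~2 %, and the nine-way rate-model comparison
ranks the true linear-primary / exponential-secondary structure first with
the minimal 4 parameters. The life-history sweep at the reference
temperate climate (annual mean 9 °C, amplitude 8 °C):

```
$ python analysis/05_life_history_sweep.py
52/52 sowings completed; winter-annual cohort (Sep-Apr, n=18): seed-set
spread 11.5 d vs sowing spread 72.6 d; T_m range 11.5-16.3 degC
$ python analysis/06_warming_and_genotypes.py
warming -4..+4: seed set 2002-07-09 -> 2002-04-08, T_m range 11.0-13.4 degC
(imposed range 8 degC)
```

Sowings spread over seven months funnel onto a ~12-day seed-set window,
and across ±4 °C of uniform warming the maturation temperature at seed
set moves by only ~2.4 °C — the buffered coincidence. Script 06 also
compares surrogate flowering-delay genotypes (later bolting → warmer
shedding → more immediately-germinable progeny at short horizons).

A CLI wraps the same operations (`seedlife synth|fit-germination|
select-model|infer-tm|fit-seedset|simulate|cohort|scenario`); see
`seedlife --help`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, by running the packaged model from scratch, the anchor
probabilities of the repositioned dormancy curves: the primary-dormancy
probability at imbibition time zero (maturation 16 °C) and the
secondary-dormancy probability at time zero (imbibition 12 °C), writing
them as JSON.

## Layout

- `src/seedlife/` — climate, phenology, germination, simulator,
  synthetic, io, cli modules
- `analysis/` — numbered narrative drivers writing tables to `results/`
- `docs/methods.md` — models, assumptions, defaults, open choices
- `tests/` — unit, property (hypothesis) and acceptance tests
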