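# oreamnos

Reproductive demography of coastal Alaska mountain goats (*Oreamnos
americanus*): age-structured logistic models of parturition and survival
with a life-history trade-off and climate covariates, information-theoretic
model selection, effect-size computation, and a stochastic climate-scenario
population projection.

The package is aimed at quantitative wildlife ecologists working with
longitudinal mark–resight data on long-lived, capital-breeding ungulates.
It answers three linked questions: how much does reproducing this year cost
a female next year, how do late-winter snow and summer temperature shift
the probability of giving birth, and which of those two climate drivers
matters more for population growth.

## The models

**Vital rates.** Each female-year outcome (parturition, offspring summer
survival, adult annual survival) is binary and modelled with a logit link:

    logit P(y_it = 1) = x_it' β + u_i,   u_i ~ N(0, σ_u²)

where `x_it` contains dummy-coded age classes (primiparous {3}, {4}, {5};
prime-aged {6–10}; senescent {11–13}, {14–16}), previous-year reproduction
R_{t−1}, its interaction with the prime-age class, late-winter (Mar–Apr)
mean snow depth (m) and mid-summer (Jul–Aug) mean temperature (°C), and
`u_i` is an individual random intercept capturing repeated measures.  The
marginal likelihood integrates `u_i` by Gauss–Hermite quadrature (21 nodes
by default) and is maximized by quasi-Newton with analytic gradients.
Candidates are compared by AICc (−2ℓ + 2k + 2k(k+1)/(n−k−1)) and Akaike
weights; random-effect structures by AICc plus boundary-corrected
likelihood-ratio tests.

**Effect sizes.** Cost of reproduction for age class a is the
percentage-point drop `100·[p(R=0) − p(R=1)]` at average climate; climate
effects are the analogous drop across a variable's observed range.

**Projection.** A post-breeding-census, sex- and age-structured (20 age
classes per sex) matrix model turns model-predicted parturition rates into
population growth.  Fecundity of an age-a female is
`F_a = S_a · m(a+1) · s₀ · (sex fraction)` with `m` the stationary
parturition rate under the previous-year feedback.  Scenarios fix snow or
temperature at its observed min/mean/max; stochastic replicates draw a
shared annual lognormal fecundity deviate (probability-scale SD 0.106) and,
optionally, coefficients from N(β̂, Σ̂).  Realized growth per replicate is
λ = (N_T/N_0)^(1/T).

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
data that emulates the study design (180 females, 3 sites, 17 years):

```bash
python analysis/01_simulate.py       # records.csv, climate.csv, truth.json
python analysis/02_fit_models.py     # selection.csv, coefficients.csv
python analysis/03_effect_sizes.py   # cost_of_reproduction.csv, climate_effects.csv
python analysis/04_project_climate.py  # scenario_summary.csv, sensitivity.json
```

`03_effect_sizes.py` prints, from the reference coefficient table:

```
age_class  p_no_prev_kid  p_prev_kid  reduction_points
        3          0.185       0.054            13.125
        4          0.552       0.236            31.652
        5          0.882       0.652            23.000
     6-10          0.823       0.806             1.750
    11-13          0.856       0.597            25.836
    14-16          0.711       0.381            33.015
-> prime-aged females lose 1.8 points; primiparous classes lose 13.1-31.7 points
```

i.e. a 3-year-old that reproduced last year is 13 percentage points less
likely to give birth this year (5% vs 19%), a 4-year-old 32 points, while
prime-aged females are essentially unaffected (2 points).
`04_project_climate.py` prints the scenario table and concludes:

```
change in mean growth across observed range: snow 6.0% vs temperature 2.1%
-> dominant driver: snow
```

deep snow years depress population growth about three times as strongly as
hot summers, because the snow coefficient is larger and snow varies more
between years.  (Absolute λ values depend on the shipped illustrative
survival schedule; the snow-versus-temperature contrast is the robust
result.)

## Layout

- `src/oreamnos/` — the library: `data_model` (types, climate pairing),
  `glmm` (likelihood, fitting, selection, diagnostics), `effects`,
  `projection`, `synthetic` (data generator), `experiments` (recovery),
  `coefficients` (reference estimates), `cli`, `config`.
- `analysis/` — numbered pipeline drivers (above).
- `oreamnos` CLI — the same pipeline as subcommands
  (`simulate` / `fit` / `effects` / `project`), each taking `--config
  <yaml>` plus overrides.
- `docs/methods.md` — modelling assumptions, parameter choices, and known
  limitations.
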