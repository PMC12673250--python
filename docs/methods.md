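# Methods

## Data model and timing conventions

A record is one female-year: parturition (kid at heel in the May birth
season), previous-year parturition status R_{t−1}, offspring summer fate
(birth → September, defined only when a birth occurred), and adult annual
survival over the biological year June–May.  Climate covariates are annual:
mean daily snow depth (m) over March–April and mean daily July–August
temperature (°C), the latter adjustable to habitat elevation with the
environmental lapse rate (−6.58 °C per 1000 m).

Parturition in year *y* is paired with snow of year *y* (late winter
immediately precedes the May births) and temperature of year *y − 1* (the
growing season in which the mother built the reserves that financed
gestation).  Adult survival over June *y* – May *y + 1* is paired with
temperature of year *y* and snow of year *y + 1*.  Rows missing a required
field are dropped per analysis and counted, never imputed.  Ages 1–2 are
retained in files but excluded from model fits: no parturition occurs at
those ages.

Age classes are dummy-coded bins; the default parturition scheme is {3},
{4}, {5}, {6–10}, {11–13}, {14–16} with 3-year-olds as the reference, and
collapsed schemes ({3–5}, {6–10}, {11–16}; {3–10}, {11–16}) serve the
survival models, where sparser data cannot support six bins.

## Random-intercept logistic likelihood

With groups *g* (individuals or sites) and intercepts u_g ~ N(0, σ_u²),
the marginal likelihood is

  L = Π_g ∫ Π_t Bernoulli(y_gt | expit(x_gt'β + u)) φ(u; 0, σ_u²) du,

evaluated by fixed-node Gauss–Hermite quadrature (21 nodes by default,
configurable).  Twenty-one nodes agree with dense numerical integration to
well below 1e−6 for σ_u ≤ 1, the regime binary vital-rate data produce;
accuracy degrades for much larger σ_u (≈1e−4 at σ_u = 2), where the node
count should be raised — the quadrature is not adaptively recentred.  A
known limitation, tested explicitly.

Optimization is L-BFGS-B on the negative log-likelihood with analytic
gradients, started at β = 0, σ_u = 0.3, with restarts at σ_u ∈ {0.05, 1.0}
if convergence fails; σ_u is bounded below by 0, so boundary estimates
σ̂_u = 0 are legitimate outcomes.  The coefficient covariance is the
inverse negative Hessian from central finite differences of the gradient;
confidence intervals are Wald (β̂ ± 1.96 SE).  A coefficient with
|β̂| > 15 flags probable complete separation (the ML estimate diverges
when a dummy cell has no outcome variation).

Model comparison uses AICc with n = number of observations (not
individuals) and Akaike weights.  Random-effect structures (none /
individual / site / individual-nested-in-site) are compared by AICc and by
likelihood-ratio tests with the 50:50 χ²₀:χ²₁ boundary mixture; nesting
individuals in sites reduces to an individual-level intercept because each
individual occupies exactly one site.  When top models sit within 2 AICc,
both are reported and a parameter whose CI spans zero is flagged
uninformative; there is no model averaging, and REML does not apply to
GLMMs.

Discrimination is the rank-statistic AUC (ties count half), banded
excellent (> 0.8) / acceptable (0.7–0.8) / low (0.5–0.7) / poor (< 0.5).
Residual diagnostics simulate replicate outcome vectors from the fitted
model (random intercepts redrawn) and compute randomized-quantile
residuals with a K-S uniformity test, plus a dispersion ratio.  The
dispersion statistic is a Pearson χ² of *within-individual outcome sums*
against their fitted expectations: per-observation Pearson residuals carry
no dispersion information for strictly binary data (a mixture of p = 0.05
and p = 0.95 rows fitted at p̂ = 0.5 leaves the per-row statistic's
expectation unchanged), whereas unmodelled heterogeneity inflates the
variance of cluster sums and is detected.

## Effect sizes

All predictions are conditional on a typical individual (random effect at
zero).  "Reduction" is a difference of probabilities × 100 (percentage
points), not relative change — this convention reproduces the
cost-of-reproduction endpoints (2 points for prime-aged, 13–32 across the
primiparous classes) from the reference coefficients, where relative change
does not.  Reference conditions default to snow 1.29 m and temperature
7.8 °C with observed ranges 0.01–2.64 m and 6.00–9.34 °C; the source
material quotes slightly different averages in different places (1.21,
1.24, 1.29 m; 7.8, 7.88, 7.89 °C), so these are configuration values, not
constants.  Climate-effect curves default to R = 1 (females that bred the
previous year).  Primiparity summaries include only females monitored from
age ≤ 3 (later entrants left-truncate the first-birth age); the SE of the
mean is sample SD/√n, 0 for n = 1.  Twinning counts litters, not kids.

## Population projection

Post-breeding census, 20 age classes per sex.  Survival occupies the
subdiagonal (terminal class non-accumulating); the fecundity row is
F_a = S_a · m(a+1) · s₀ · (sex fraction), with s₀ the neonate-to-census
survival.  The age-specific parturition rate m feeds back on itself
through R_{t−1}; the projection uses the stationary rate of that two-state
chain, p* = p₀/(1 + p₀ − p₁), in closed form, so the matrix needs no
individual reproduction histories.

The survival schedule is a configuration input.  The shipped default is
*illustrative and partly synthetic*: adult female values derive from the
fitted survival model at mean snow (0.944 ages 3–5, 0.841 ages 6–10, 0.669
ages 11+), while kid (0.70), yearling (0.85), two-year-old (0.92) and male
(95% of female) values are plausible placeholders chosen to give a
near-stationary population (λ ≈ 1.01) at mean climate.  Absolute growth
rates under this schedule are therefore illustrative; the snow-versus-
temperature *contrast* is the supported result, and it is insensitive to
the schedule because both scenarios share it.

Scenarios fix one climate variable at its observed min/mean/max with the
other at its mean.  Environmental stochasticity is a lognormal fecundity
deviate with probability-scale SD 0.106 (interannual variation in observed
fecundity), matched on the probability scale per age
(μ = log(m²/√(m² + SD²)), s² = log(1 + SD²/m²)), driven by one
standard-normal draw per year shared across ages, clamped to [0, 1].
Parameter uncertainty (coefficients ~ MVN(β̂, Σ̂)) is a switch, off by
default so the deterministic core is exactly reproducible; when reference
coefficients lacking a full covariance are used, sampling falls back to a
diagonal covariance from the SEs.  Runs start from 100 individuals at the
stable age distribution of the mean-climate matrix (power iteration,
tolerance 1e−10; reducible matrices without a dominant eigenvalue raise an
error).  Realized λ is the geometric mean (N_T/N_0)^(1/T) over a 30-year
horizon; default replicate count 10,000 (1,000–2,000 suffices for the
ordering result and is what the analysis scripts use to keep runtimes in
seconds); replicate r draws from a generator seeded (seed, r), so results
are reproducible and order-independent.  A replicate that reaches zero
records λ = 0 and is retained; quasi-extinction is fewer than 2 females at
any point.  Mean λ under fecundity noise sits slightly below the
deterministic eigenvalue (Jensen penalty of geometric-mean growth), a
property the tests assert.

Per-variable sensitivity is Δλ% = 100 (λ̄_fav − λ̄_unfav)/λ̄_unfav between
the favourable and unfavourable extremes; the dominant driver is the
variable with the larger Δλ%.

## Synthetic data generator

The generator emulates the study design: 180 females across 3 sites over
17 years, entry ages 1–10 weighted toward ages 3–5 with some mass at older
ages (weights 0.05, 0.08, 0.14, 0.16, 0.14, 0.11, 0.09, 0.08, 0.08, 0.07 —
purely young-adult entry would leave the senescent age classes nearly
empty and make refits separate), monitoring spans geometric (p = 0.08)
truncated by study end and death.  Outcomes are drawn from the reference
coefficient tables with per-model individual intercepts, σ_u = 0.7 (not
estimable from published tables; chosen to give modest within-individual
correlation while keeping marginal rates realistic, and always recorded in
the truth sidecar).  Parturition conditions on the female's true previous
outcome; her first R is drawn from the stationary frequency *conditional
on her own intercept* — seeding at u = 0 induces a dynamic-panel
initial-conditions bias that attenuates the previous-reproduction
coefficient by 0.1–0.2 in recovery experiments, and the conditional draw
removes it.  Missingness is applied last: previous-year status is unknown
in the first monitored year (capture-year missingness), and any year's kid
status is equivocal with probability 0.05, which also hides the next
year's R.  The defaults yield ≈ 630 determined occasions (3.5 per female)
and ≈ 410 usable parturition rows, close to the study's 640 and 459.
Twinning is marked at 1.5% of litters without altering the binary outcome.

What the generator does *not* emulate: spatial structure beyond a site
label, observation error beyond the two missingness channels, density
dependence, climate autocorrelation (years are exchangeable draws), and
individual heterogeneity beyond a single normal intercept.  Passing
recovery tests therefore show the estimator is consistent for data meeting
the model's assumptions at study scale — not that real monitoring data
meet them.

## Recovery experiment

200 synthetic datasets at study scale, each refit with the full model;
per-dataset seeds derive from one base seed.  Non-converged or
separation-flagged fits (≈ 1–5%) are excluded from summaries, with counts
reported — under separation the ML estimate does not exist.  The snow and
previous-reproduction coefficients are recovered with |bias| < 0.05 and
Wald CI coverage ≈ 0.94–0.96; coverage is near-nominal for every
coefficient.  The sparse senescent age dummies show the expected
small-sample ML bias away from zero (up to ≈ 0.2 on the logit scale in
≈ 15-observation cells), a property of the estimator at this sample size,
not a defect of the generator.

## Numerical conventions

Ties in model selection order by AICc then by fewer parameters.  Design
matrices are checked for full rank before fitting (collinear columns
reported by name).  Probabilities assembled into projection matrices are
clamped to [0, 1] with a warning counting affected entries.  Zero
fecundities stay exactly zero under lognormal noise.  All CSV outputs
carry `# seed=` and `# config_hash=` header comments and round-trip
losslessly through the package readers.
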