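"""Synthetic longitudinal mark-resight data with the study's structure.

Generates individual-year records for marked female mountain goats across
sites and years, with binary parturition, offspring summer fate and adult
annual survival drawn from the reference logistic models (individual random
intercepts on the logit scale), plus an annual climate series.  The
generator's defaults emulate the study design: 180 females, 3 sites, 17
years, ages 1-16, repeated measures, climate within the observed ranges
(snow 0.01-2.64 m, temperature 6.00-9.34 degC).

The generating truth (coefficients, random-intercept SD, per-individual
intercepts, climate) is returned alongside the records so recovery
experiments can compare estimates against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import coefficients as coef
from .data_model import (
    DEFAULT_AGE_CLASSES,
    OFFSPRING_AGE_CLASSES,
    SURVIVAL_AGE_CLASSES,
)
from .glmm import FittedModel

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "generate_climate"]


@dataclass
class GeneratorConfig:
    """Study-design and generating-model parameters.

    Entry ages are weighted toward young adults (capture favours ages 2-5);
    monitoring spans are geometric with mean ~3.3 observed years per
    female, close to the study's 3.5 occasions/female.  Previous-year
    reproduction in a female's first monitored year is unknown with
    probability ``first_year_prev_missing`` (capture-year missingness);
    independently, any year's parturition status may be unassessable
    ("equivocal") with probability ``equivocal_rate``.
    """

    n_individuals: int = 180
    n_sites: int = 3
    n_years: int = 17
    start_year: int = 2005
    sigma_u: float = 0.7
    entry_ages: tuple[int, ...] = tuple(range(1, 11))
    entry_age_weights: tuple[float, ...] = (
        0.05, 0.08, 0.14, 0.16, 0.14, 0.11, 0.09, 0.08, 0.08, 0.07,
    )
    span_geometric_p: float = 0.08
    first_year_prev_missing: float = 1.0
    equivocal_rate: float = 0.05
    twinning_rate: float = 0.015
    snow_range: tuple[float, float] = (0.01, 2.64)
    temp_range: tuple[float, float] = (6.00, 9.34)
    climate_mode: str = "uniform"
    climate_series: Optional[pd.DataFrame] = None
    parturition_model: FittedModel = field(default_factory=coef.parturition_model)
    adult_survival_model: FittedModel = field(default_factory=coef.adult_survival_model)
    offspring_survival_model: FittedModel = field(default_factory=coef.offspring_survival_model)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        for p in (
            self.first_year_prev_missing,
            self.equivocal_rate,
            self.twinning_rate,
            self.span_geometric_p,
        ):
            if not 0 <= p <= 1:
                raise ValueError("rates must be probabilities")
        if len(self.entry_age_weights) != len(self.entry_ages):
            raise ValueError("entry age weights must match entry ages")


@dataclass
class SyntheticDataset:
    records: pd.DataFrame
    climate: pd.DataFrame  # columns year, snow, temp
    truth: dict


def generate_climate(
    n_years: int,
    snow_range: tuple[float, float] = (0.01, 2.64),
    temp_range: tuple[float, float] = (6.00, 9.34),
    mode: str = "uniform",
    seed: int = 0,
    start_year: int = 2005,
    series: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Annual climate series within configured ranges.

    Modes: ``uniform`` draws each year independently within the range;
    ``resample`` bootstraps rows of a supplied empirical series; ``fixed``
    repeats the supplied values (cycled to length).
    """
    if not (snow_range[0] < snow_range[1] and temp_range[0] < temp_range[1]):
        raise ValueError("invalid climate ranges")
    years = np.arange(start_year, start_year + n_years)
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        snow = rng.uniform(*snow_range, size=n_years)
        temp = rng.uniform(*temp_range, size=n_years)
    elif mode in ("resample", "fixed"):
        if series is None or len(series) == 0:
            raise ValueError(f"mode {mode!r} requires a supplied series")
        src = series.rename(columns={"snow_m": "snow", "temp_c": "temp"})
        if mode == "resample":
            idx = rng.integers(0, len(src), size=n_years)
        else:
            idx = np.arange(n_years) % len(src)
        snow = src["snow"].to_numpy()[idx]
        temp = src["temp"].to_numpy()[idx]
    else:
        raise ValueError(f"unknown climate mode {mode!r}")
    return pd.DataFrame({"year": years, "snow": snow, "temp": temp})


def _eta(fit: FittedModel, terms: dict[str, float]) -> float:
    eta = 0.0
    for name, value in terms.items():
        if name in fit.params.index:
            eta += fit.params[name] * value
    return eta


def _parturition_eta(
    fit: FittedModel, age: int, prev: int, snow: float, temp: float
) -> Optional[float]:
    label = fit.spec.age_spec.assign(age)
    if label is None:
        return None
    terms = {"Intercept": 1.0, "prev_repro": float(prev), "snow": snow, "temp": temp}
    if label != fit.spec.age_spec.reference:
        terms[f"age[{label}]"] = 1.0
    terms[f"prev_repro:age[{label}]"] = float(prev)
    return _eta(fit, terms)


def _survival_eta(fit: FittedModel, age: int, snow: float) -> float:
    spec = fit.spec.age_spec
    label = spec.assign(min(max(age, spec.min_age), spec.max_age))
    terms = {"Intercept": 1.0, "snow": snow}
    if label != spec.reference:
        terms[f"age[{label}]"] = 1.0
    return _eta(fit, terms)


def _offspring_eta(fit: FittedModel, age: int) -> float:
    spec = fit.spec.age_spec
    label = spec.assign(min(max(age, spec.min_age), spec.max_age))
    terms = {"Intercept": 1.0}
    if label != spec.reference:
        terms[f"age[{label}]"] = 1.0
    return _eta(fit, terms)


def _stationary_prev(
    fit: FittedModel, age: int, snow: float, temp: float, u: float = 0.0
) -> float:
    """Stationary reproduction frequency used to seed R at first observation.

    Computed conditional on the female's own random intercept ``u`` so the
    initial state carries the same heterogeneity as the rest of her series.
    """
    eta0 = _parturition_eta(fit, age, 0, snow, temp)
    eta1 = _parturition_eta(fit, age, 1, snow, temp)
    if eta0 is None:
        return 0.0
    p0, p1 = expit(eta0 + u), expit(eta1 + u)
    return float(p0 / (1.0 + p0 - p1))


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Simulate one longitudinal dataset under the configured truth.

    Per female: entry year/age, one random intercept per outcome model
    (u ~ N(0, sigma_u^2)); per year, parturition from the parturition model
    conditioned on the previous year's outcome (ages 1-2 never reproduce),
    offspring summer fate conditional on parturition, and adult survival
    (death ends the series).  Missingness is applied last.  Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    # climate needs two years before the study (previous-summer temperature
    # of the stationary seeding year) and one after (late-winter snow of the
    # final survival year)
    clim = generate_climate(
        config.n_years + 3,
        config.snow_range,
        config.temp_range,
        mode=config.climate_mode,
        seed=config.seed + 1,
        start_year=config.start_year - 2,
        series=config.climate_series,
    )
    snow = dict(zip(clim["year"], clim["snow"]))
    temp = dict(zip(clim["year"], clim["temp"]))
    end_year = config.start_year + config.n_years - 1

    pm, sm, om = (
        config.parturition_model,
        config.adult_survival_model,
        config.offspring_survival_model,
    )
    rows = []
    u_truth = {}
    for i in range(config.n_individuals):
        iid = f"F{i:03d}"
        site = f"site{rng.integers(config.n_sites) + 1}"
        entry_year = int(rng.integers(config.start_year, end_year + 1))
        entry_age = int(rng.choice(config.entry_ages, p=config.entry_age_weights))
        span = int(rng.geometric(config.span_geometric_p))
        u_part = rng.normal(0.0, config.sigma_u)
        u_surv = rng.normal(0.0, config.sigma_u)
        u_off = rng.normal(0.0, config.sigma_u)
        u_truth[iid] = {"parturition": u_part, "survival": u_surv, "offspring": u_off}

        prev = int(
            rng.random()
            < _stationary_prev(
                pm, entry_age - 1, snow[entry_year - 1], temp[entry_year - 2], u_part
            )
        ) if entry_age >= 4 else 0
        first = True
        prev_known = True
        age, year = entry_age, entry_year
        while year <= end_year and age <= 16 and (year - entry_year) < span:
            eta = _parturition_eta(pm, age, prev, snow[year], temp[year - 1])
            part = int(rng.random() < expit(eta + u_part)) if eta is not None else 0
            twins = int(part == 1 and rng.random() < config.twinning_rate)
            off = (
                int(rng.random() < expit(_offspring_eta(om, age) + u_off))
                if part == 1
                else None
            )
            surv = int(rng.random() < expit(_survival_eta(sm, age, snow[year + 1]) + u_surv))

            prev_out = prev if prev_known else None
            if first and rng.random() < config.first_year_prev_missing:
                prev_out = None
            part_out, off_out, twins_out = part, off, twins
            if eta is not None and rng.random() < config.equivocal_rate:
                part_out, off_out, twins_out = None, None, None
            rows.append(
                {
                    "individual_id": iid,
                    "site": site,
                    "year": year,
                    "age": age,
                    "parturition": part_out,
                    "prev_reproduction": prev_out,
                    "offspring_summer_survival": off_out,
                    "adult_annual_survival": surv,
                    "twins": twins_out,
                }
            )
            if surv == 0:
                break
            # the biological process always conditions on the true outcome;
            # observation missingness only affects what gets recorded
            prev = part
            prev_known = part_out is not None
            first = False
            age += 1
            year += 1

    records = pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "site",
            "year",
            "age",
            "parturition",
            "prev_reproduction",
            "offspring_summer_survival",
            "adult_annual_survival",
            "twins",
        ],
    )
    truth = {
        "sigma_u": config.sigma_u,
        "coefficients": {
            "parturition": pm.params.to_dict(),
            "adult_survival": sm.params.to_dict(),
            "offspring_survival": om.params.to_dict(),
        },
        "random_intercepts": u_truth,
        "seed": config.seed,
    }
    study_clim = clim[
        (clim["year"] >= config.start_year - 1) & (clim["year"] <= end_year + 1)
    ].reset_index(drop=True)
    return SyntheticDataset(records=records, climate=study_clim, truth=truth)
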