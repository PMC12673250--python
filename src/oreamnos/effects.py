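"""Headline effect sizes and descriptive life-history summaries.

Turns fitted coefficient tables into the quantities of biological interest:
age-specific parturition probabilities for a typical individual (random
effect at zero), the cost of reproduction (percentage-point drop in
parturition probability after a successful previous year), climate effects
(probability drop across the observed range of snow or temperature), and
descriptive statistics (twinning rate, age of primiparity).

"Reduction" is always in percentage points — 100 times the difference of
two probabilities — not relative change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .glmm import FittedModel

__all__ = [
    "ReferenceConditions",
    "predict_probability",
    "cost_of_reproduction",
    "climate_effect",
    "life_history_summaries",
]


@dataclass(frozen=True)
class ReferenceConditions:
    """Average conditions and observed climate ranges used for predictions.

    Defaults are the study system's late-winter snow depth and mid-summer
    temperature averages, with ranges spanning the observed inter-annual
    extremes.
    """

    snow_ref: float = 1.29
    temp_ref: float = 7.8
    snow_range: tuple[float, float] = (0.01, 2.64)
    temp_range: tuple[float, float] = (6.00, 9.34)

    def __post_init__(self) -> None:
        for lo, hi in (self.snow_range, self.temp_range):
            if not lo < hi:
                raise ValueError("range min must be < max")


def _coef(fit: FittedModel, name: str) -> float:
    return float(fit.params.get(name, 0.0))


def predict_probability(
    fit: FittedModel,
    age_class: str,
    prev_repro: int = 0,
    snow: Optional[float] = None,
    temp: Optional[float] = None,
    ref: ReferenceConditions = ReferenceConditions(),
) -> float:
    """Typical-individual probability for one age class and covariate setting.

    Applies the inverse logit to intercept + age dummy + previous-
    reproduction effect (plus any age-specific interaction) + climate terms,
    with the random effect at zero.  Covariates default to the reference
    conditions.  A covariate more than twice the observed span outside its
    range triggers a warning (extrapolation), not an error.
    """
    spec = fit.spec
    if age_class not in spec.age_spec.labels:
        raise ValueError(f"age class {age_class!r} not in model scheme")
    snow = ref.snow_ref if snow is None else snow
    temp = ref.temp_ref if temp is None else temp
    for val, (lo, hi), label in (
        (snow, ref.snow_range, "snow"),
        (temp, ref.temp_range, "temp"),
    ):
        span = hi - lo
        if val < lo - 2 * span or val > hi + 2 * span:
            warnings.warn(f"{label}={val} far outside observed range", stacklevel=2)
    eta = _coef(fit, "Intercept")
    if age_class != spec.age_spec.reference:
        eta += _coef(fit, f"age[{age_class}]")
    eta += _coef(fit, "prev_repro") * prev_repro
    eta += _coef(fit, f"prev_repro:age[{age_class}]") * prev_repro
    if "snow" in fit.params.index:
        eta += _coef(fit, "snow") * snow
    if "temp" in fit.params.index:
        eta += _coef(fit, "temp") * temp
    return float(1.0 / (1.0 + np.exp(-eta)))


def cost_of_reproduction(
    fit: FittedModel, ref: ReferenceConditions = ReferenceConditions()
) -> pd.DataFrame:
    """Percentage-point reduction in parturition probability after a kid year.

    For each age class, probability with and without previous-year
    reproduction at reference climate, and the reduction
    100*(p(no kid) - p(kid)).  Attributes ``primiparous_min``,
    ``primiparous_max`` (over classes containing only ages 3-5) and
    ``prime_reduction`` are attached to the frame's ``attrs``.
    """
    if "prev_repro" not in fit.params.index:
        raise ValueError("model has no previous-reproduction term")
    rows = []
    for label, lo, hi in fit.spec.age_spec.bins:
        p0 = predict_probability(fit, label, 0, ref=ref)
        p1 = predict_probability(fit, label, 1, ref=ref)
        rows.append(
            {
                "age_class": label,
                "p_no_prev_kid": p0,
                "p_prev_kid": p1,
                "reduction_points": 100 * (p0 - p1),
                "ages": (lo, hi),
            }
        )
    out = pd.DataFrame(rows)
    primi = out[[lo >= 3 and hi <= 5 for lo, hi in out["ages"]]]
    prime = out[[lo == 6 and hi == 10 for lo, hi in out["ages"]]]
    out.attrs["primiparous_min"] = float(primi["reduction_points"].min()) if len(primi) else np.nan
    out.attrs["primiparous_max"] = float(primi["reduction_points"].max()) if len(primi) else np.nan
    out.attrs["prime_reduction"] = float(prime["reduction_points"].iloc[0]) if len(prime) else np.nan
    return out.drop(columns="ages")


def climate_effect(
    fit: FittedModel,
    variable: str,
    ref: ReferenceConditions = ReferenceConditions(),
    prev_repro: int = 1,
) -> pd.DataFrame:
    """Probability change across a climate variable's observed range.

    Per age class, probability at the variable's minimum and maximum with
    the other climate variable at its reference and previous-year
    reproduction as given (default 1: females that reproduced the previous
    year).  Reduction is in percentage points, low-end minus high-end.
    """
    if variable not in ("snow", "temp"):
        raise ValueError("variable must be 'snow' or 'temp'")
    if variable not in fit.params.index:
        raise ValueError(f"model has no {variable} term")
    lo, hi = ref.snow_range if variable == "snow" else ref.temp_range
    rows = []
    for label in fit.spec.age_spec.labels:
        kw_lo = {variable: lo}
        kw_hi = {variable: hi}
        p_lo = predict_probability(fit, label, prev_repro, ref=ref, **kw_lo)
        p_hi = predict_probability(fit, label, prev_repro, ref=ref, **kw_hi)
        rows.append(
            {
                "age_class": label,
                "variable": variable,
                "var_low": lo,
                "var_high": hi,
                "p_at_low": p_lo,
                "p_at_high": p_hi,
                "reduction_points": 100 * (p_lo - p_hi),
            }
        )
    return pd.DataFrame(rows)


def life_history_summaries(records: pd.DataFrame) -> dict:
    """Descriptive reproductive statistics from a records table.

    Returns parturition-event and twinning counts (twin litters as a
    percentage of parturition events, one decimal), the distribution of
    age at first birth among females monitored from age <= 3, with mean
    and standard error (sample SD / sqrt(n); 0 when n = 1), and the count
    of monitored occasions (rows with a determined parturition status).
    """
    if len(records) == 0:
        raise ValueError("records table is empty")
    det = records[records["parturition"].notna()]
    events = int((det["parturition"] == 1).sum())
    if "twins" in records.columns:
        twin_litters = int((det.get("twins") == 1).sum())
        twin_pct = round(100 * twin_litters / events, 1) if events else np.nan
    else:
        twin_litters, twin_pct = None, None

    # primiparity: females whose monitoring starts at age <= 3
    first_birth_ages: list[int] = []
    for _, g in det.sort_values("year").groupby("individual_id"):
        if g["age"].iloc[0] > 3:
            continue
        births = g[g["parturition"] == 1]
        if len(births):
            first_birth_ages.append(int(births["age"].iloc[0]))
    if first_birth_ages:
        arr = np.array(first_birth_ages, dtype=float)
        mean = float(arr.mean())
        se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        dist = {int(a): int(c) for a, c in zip(*np.unique(arr, return_counts=True))}
        primiparity = {
            "n": len(arr),
            "mean": mean,
            "se": se,
            "distribution": dist,
        }
    else:
        primiparity = None

    return {
        "n_occasions": int(len(det)),
        "n_parturition_events": events,
        "twin_litters": twin_litters,
        "twinning_percent": twin_pct,
        "primiparity": primiparity,
    }
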