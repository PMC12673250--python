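"""Reference coefficient estimates for the coastal Alaska mountain goat system.

These are the fitted logistic-regression coefficient tables (logit scale)
for the three vital-rate models of the study system.  They serve two roles:

* defaults for the synthetic-data generator (the generative truth), and
* inputs for effect-size computation and the population projection when no
  refit is requested.

Standard errors accompany each estimate; absent a published coefficient
covariance, sampling uses a diagonal covariance built from the SEs.

Model structure (all logit link, individual random intercept in the study):

* ``parturition`` — six age classes (reference: 3-year-olds that did not
  reproduce the previous year), previous-year reproduction, its interaction
  with the prime-aged (6-10 y) class, late-winter snow depth (m) and
  previous-summer temperature (degC).
* ``adult_survival`` — three collapsed age classes (reference 3-5 y) and
  snow depth.
* ``offspring_survival`` — maternal age (reference: mothers 3-10 y).
"""

from __future__ import annotations

from .data_model import (
    DEFAULT_AGE_CLASSES,
    OFFSPRING_AGE_CLASSES,
    SURVIVAL_AGE_CLASSES,
)
from .glmm import FittedModel, ModelSpec

__all__ = [
    "PARTURITION_SPEC",
    "ADULT_SURVIVAL_SPEC",
    "OFFSPRING_SURVIVAL_SPEC",
    "parturition_model",
    "adult_survival_model",
    "offspring_survival_model",
]

PARTURITION_SPEC = ModelSpec(
    outcome="parturition",
    age_spec=DEFAULT_AGE_CLASSES,
    terms=("age", "prev_repro", "snow", "temp", "prev_repro:age[6-10]"),
    random="individual",
    name="parturition: age + prev_repro * prime + snow + temp",
)

ADULT_SURVIVAL_SPEC = ModelSpec(
    outcome="adult_survival",
    age_spec=SURVIVAL_AGE_CLASSES,
    terms=("age", "snow"),
    random="individual",
    name="adult survival: age + snow",
)

OFFSPRING_SURVIVAL_SPEC = ModelSpec(
    outcome="offspring_survival",
    age_spec=OFFSPRING_AGE_CLASSES,
    terms=("age",),
    random="individual_in_site",
    name="offspring summer survival: maternal age",
)

_PARTURITION_COEFS = {
    "Intercept": (0.993, 1.463),
    "age[4]": (1.693, 0.844),
    "age[5]": (3.499, 0.927),
    "age[6-10]": (3.023, 0.869),
    "age[11-13]": (3.264, 0.939),
    "age[14-16]": (2.382, 1.038),
    "prev_repro": (-1.386, 0.502),
    "snow": (-0.680, 0.187),
    "temp": (-0.205, 0.144),
    "prev_repro:age[6-10]": (1.270, 0.569),
}

_ADULT_SURVIVAL_COEFS = {
    "Intercept": (3.315, 0.577),
    "age[6-10]": (-1.164, 0.546),
    "age[11-16]": (-2.127, 0.582),
    "snow": (-0.392, 0.185),
}

_OFFSPRING_SURVIVAL_COEFS = {
    "Intercept": (2.206, 0.640),
    "age[11-16]": (-0.703, 0.398),
}


def _build(spec: ModelSpec, table: dict[str, tuple[float, float]]) -> FittedModel:
    params = {k: v[0] for k, v in table.items()}
    se = {k: v[1] for k, v in table.items()}
    return FittedModel.from_coefficients(spec, params, se)


def parturition_model() -> FittedModel:
    """Reference parturition model as a FittedModel (random effect at zero)."""
    return _build(PARTURITION_SPEC, _PARTURITION_COEFS)


def adult_survival_model() -> FittedModel:
    return _build(ADULT_SURVIVAL_SPEC, _ADULT_SURVIVAL_COEFS)


def offspring_survival_model() -> FittedModel:
    return _build(OFFSPRING_SURVIVAL_SPEC, _OFFSPRING_SURVIVAL_COEFS)
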