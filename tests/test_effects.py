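import numpy as np
import pandas as pd
import pytest

from oreamnos.coefficients import (
    OFFSPRING_SURVIVAL_SPEC,
    PARTURITION_SPEC,
    offspring_survival_model,
    parturition_model,
)
from oreamnos.effects import (
    ReferenceConditions,
    climate_effect,
    cost_of_reproduction,
    life_history_summaries,
    predict_probability,
)
from oreamnos.glmm import FittedModel


@pytest.fixture(scope="module")
def part_model():
    return parturition_model()


class TestPredictProbability:
    def test_prime_age_at_reference_conditions(self, part_model):
        # inverse-logit of 0.993 + 3.023 - 0.680*1.29 - 0.205*7.8
        p = predict_probability(part_model, "6-10", prev_repro=0)
        assert p == pytest.approx(0.823, abs=0.001)

    def test_all_zero_coefficients_give_half(self):
        zero = FittedModel.from_coefficients(
            PARTURITION_SPEC, {k: 0.0 for k in parturition_model().params.index}
        )
        assert predict_probability(zero, "4", 1) == pytest.approx(0.5)

    def test_offspring_survival_young_mothers(self):
        p = predict_probability(offspring_survival_model(), "3-10")
        assert round(100 * p, 1) == 90.1

    def test_unknown_age_class_rejected(self, part_model):
        with pytest.raises(ValueError):
            predict_probability(part_model, "17-20")

    def test_extrapolation_warns(self, part_model):
        with pytest.warns(UserWarning, match="outside observed range"):
            predict_probability(part_model, "4", snow=25.0)

    @pytest.mark.parametrize("age_class", ["3", "4", "5", "6-10", "11-13", "14-16"])
    def test_monotone_decreasing_in_snow(self, part_model, age_class):
        grid = np.linspace(0.01, 2.64, 15)
        probs = [
            predict_probability(part_model, age_class, 1, snow=s) for s in grid
        ]
        assert np.all(np.diff(probs) < 0)


class TestCostOfReproduction:
    def test_abstract_endpoints(self, part_model):
        cost = cost_of_reproduction(part_model)
        assert round(cost.attrs["prime_reduction"]) == 2
        assert round(cost.attrs["primiparous_min"]) == 13
        assert round(cost.attrs["primiparous_max"]) == 32

    def test_zero_cost_terms_give_zero_reduction(self):
        params = parturition_model().params.copy()
        params["prev_repro"] = 0.0
        params["prev_repro:age[6-10]"] = 0.0
        f = FittedModel.from_coefficients(PARTURITION_SPEC, params.to_dict())
        cost = cost_of_reproduction(f)
        assert np.allclose(cost["reduction_points"], 0.0)

    def test_prime_reduction_uses_both_terms(self):
        # interaction exactly cancelling the main effect zeroes the prime
        # class reduction while others stay positive
        params = parturition_model().params.copy()
        params["prev_repro:age[6-10]"] = -params["prev_repro"]
        f = FittedModel.from_coefficients(PARTURITION_SPEC, params.to_dict())
        cost = cost_of_reproduction(f).set_index("age_class")
        assert cost.loc["6-10", "reduction_points"] == pytest.approx(0.0, abs=1e-12)
        assert cost.loc["4", "reduction_points"] > 10

    def test_requires_prev_repro_term(self):
        f = offspring_survival_model()
        with pytest.raises(ValueError):
            cost_of_reproduction(f)

    def test_logit_and_probability_scales_agree(self, part_model):
        # reductions computed via the linear predictor then transformed
        # must equal the direct probability differences
        from scipy.special import expit, logit

        cost = cost_of_reproduction(part_model)
        for _, row in cost.iterrows():
            d = expit(logit(row["p_no_prev_kid"])) - expit(logit(row["p_prev_kid"]))
            assert row["reduction_points"] == pytest.approx(100 * d, abs=1e-9)


class TestClimateEffect:
    def test_snow_effect_prime_aged(self, part_model):
        eff = climate_effect(part_model, "snow").set_index("age_class")
        assert eff.loc["6-10", "p_at_low"] == pytest.approx(0.908, abs=0.001)
        assert eff.loc["6-10", "p_at_high"] == pytest.approx(0.624, abs=0.001)

    def test_zero_width_range_gives_zero_effect(self, part_model):
        ref = ReferenceConditions(snow_range=(1.29, 1.29 + 1e-12))
        eff = climate_effect(part_model, "snow", ref)
        assert np.allclose(eff["reduction_points"], 0.0, atol=1e-6)

    def test_missing_variable_rejected(self):
        f = offspring_survival_model()
        with pytest.raises(ValueError):
            climate_effect(f, "snow")


def _primiparity_records():
    """24 females monitored from age 3, first births at {3:5, 4:13, 5:5, 6:1}."""
    rows = []
    first_births = [3] * 5 + [4] * 13 + [5] * 5 + [6] * 1
    for i, fb in enumerate(first_births):
        for age in range(3, fb + 1):
            rows.append(
                {
                    "individual_id": f"P{i}",
                    "site": "s1",
                    "year": 2000 + age,
                    "age": age,
                    "parturition": int(age == fb),
                    "prev_reproduction": 0,
                    "offspring_summer_survival": None,
                    "adult_annual_survival": 1,
                    "twins": 0,
                }
            )
    return pd.DataFrame(rows)


class TestLifeHistorySummaries:
    def test_primiparity_distribution(self):
        s = life_history_summaries(_primiparity_records())
        pp = s["primiparity"]
        assert pp["n"] == 24
        assert pp["distribution"] == {3: 5, 4: 13, 5: 5, 6: 1}
        assert round(pp["mean"], 1) == 4.1
        assert round(100 * pp["distribution"][4] / pp["n"]) == 54

    def test_twinning_rate(self):
        # 405 parturition events, 6 twin litters
        rows = []
        for i in range(405):
            rows.append(
                {
                    "individual_id": f"T{i}",
                    "site": "s1",
                    "year": 2010,
                    "age": 6,
                    "parturition": 1,
                    "prev_reproduction": 0,
                    "offspring_summer_survival": None,
                    "adult_annual_survival": 1,
                    "twins": int(i < 6),
                }
            )
        s = life_history_summaries(pd.DataFrame(rows))
        assert s["n_parturition_events"] == 405
        assert s["twinning_percent"] == 1.5

    def test_single_female_single_birth(self):
        rec = _primiparity_records()
        one = rec[rec["individual_id"] == "P6"]  # first birth at 4
        s = life_history_summaries(one)
        assert s["primiparity"]["mean"] == 4.0
        assert s["primiparity"]["se"] == 0.0

    def test_permutation_invariance(self):
        rec = _primiparity_records()
        shuffled = rec.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = life_history_summaries(rec)
        b = life_history_summaries(shuffled)
        assert a == b

    def test_no_eligible_females_marked_unavailable(self):
        rec = _primiparity_records()
        older = rec[rec["age"] >= 4].copy()  # nobody monitored from <= 3
        # females first seen at 4+ are excluded from primiparity
        older = older[older.groupby("individual_id")["age"].transform("min") > 3]
        s = life_history_summaries(older)
        assert s["primiparity"] is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            life_history_summaries(_primiparity_records().iloc[0:0])
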