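import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from oreamnos.coefficients import PARTURITION_SPEC
from oreamnos.data_model import DEFAULT_AGE_CLASSES
from oreamnos.glmm import (
    FittedModel,
    ModelSpec,
    aicc_compare,
    assess_random_effects,
    auc,
    fit,
    log_likelihood,
    residual_diagnostics,
)


def brute_force_loglik(beta, sigma, X, y, group_idx, n_grid=20001):
    """Dense-trapezoid integration oracle for the random-intercept likelihood."""
    u = np.linspace(-8 * sigma, 8 * sigma, n_grid)
    phi = stats.norm.pdf(u, 0, sigma)
    total = 0.0
    for g in np.unique(group_idx):
        m = group_idx == g
        eta = X[m] @ beta
        p = expit(eta[:, None] + u[None, :])
        lik = np.prod(np.where(y[m][:, None] == 1, p, 1 - p), axis=0)
        total += np.log(np.trapezoid(lik * phi, u))
    return total


class TestLogLikelihood:
    def test_intercept_only_at_zero_is_n_log_half(self):
        y = np.array([0, 1, 1, 0, 1, 0], dtype=float)
        X = np.ones((6, 1))
        ll = log_likelihood(np.zeros(1), 0.0, X, y)
        assert ll == pytest.approx(-6 * np.log(2))

    def test_sigma_zero_degenerates_to_fixed_effects(self, grouped_bernoulli):
        d = grouped_bernoulli
        ll_fixed = log_likelihood(d["beta"], 0.0, d["X"], d["y"])
        ll_re = log_likelihood(d["beta"], 0.0, d["X"], d["y"], d["group_idx"])
        assert ll_re == pytest.approx(ll_fixed, abs=1e-12)

    def test_quadrature_matches_dense_integration(self, grouped_bernoulli):
        d = grouped_bernoulli
        ll_q = log_likelihood(
            d["beta"], d["sigma"], d["X"], d["y"], d["group_idx"], n_nodes=21
        )
        ll_bf = brute_force_loglik(
            d["beta"], d["sigma"], d["X"], d["y"], d["group_idx"]
        )
        assert ll_q == pytest.approx(ll_bf, abs=1e-6)

    def test_node_count_converged(self, grouped_bernoulli):
        d = grouped_bernoulli
        ll21 = log_likelihood(d["beta"], d["sigma"], d["X"], d["y"], d["group_idx"], n_nodes=21)
        ll31 = log_likelihood(d["beta"], d["sigma"], d["X"], d["y"], d["group_idx"], n_nodes=31)
        assert abs(ll21 - ll31) < 1e-6

    def test_invalid_params_rejected(self, grouped_bernoulli):
        d = grouped_bernoulli
        with pytest.raises(ValueError):
            log_likelihood(np.array([np.nan, 0.0]), 0.5, d["X"], d["y"], d["group_idx"])
        with pytest.raises(ValueError):
            log_likelihood(d["beta"], -0.1, d["X"], d["y"], d["group_idx"])


def _toy_table(n, rng, beta_snow=-0.7, intercept=1.0):
    snow = rng.uniform(0, 3, n)
    p = expit(intercept + beta_snow * snow)
    return pd.DataFrame(
        {
            "y": (rng.random(n) < p).astype(int),
            "snow": snow,
            "individual_id": [f"i{k}" for k in range(n)],
            "site": "s1",
        }
    )


SNOW_ONLY = ModelSpec(
    outcome="parturition", age_spec=DEFAULT_AGE_CLASSES, terms=("snow",), random="none"
)


class TestFit:
    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(5)
        table = _toy_table(5000, rng)
        f = fit(SNOW_ONLY, table)
        se = f.se
        assert abs(f.params["Intercept"] - 1.0) < 3 * se["Intercept"]
        assert abs(f.params["snow"] - (-0.7)) < 3 * se["snow"]
        assert f.converged

    def test_matches_irls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        table = _toy_table(800, rng)
        f = fit(SNOW_ONLY, table)
        X = sm.add_constant(table["snow"].to_numpy())
        ref = sm.GLM(table["y"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert f.params["Intercept"] == pytest.approx(ref.params[0], abs=1e-6)
        assert f.params["snow"] == pytest.approx(ref.params[1], abs=1e-6)
        assert f.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_separation_flagged(self):
        rng = np.random.default_rng(7)
        table = _toy_table(60, rng)
        table["y"] = 1
        table.loc[0, "y"] = 0
        table.loc[0, "snow"] = 99.0  # the lone failure is perfectly separable
        with pytest.warns(UserWarning, match="separation"):
            f = fit(SNOW_ONLY, table)
        assert f.separation

    def test_rank_deficient_design_reports_columns(self):
        rng = np.random.default_rng(8)
        table = _toy_table(100, rng)
        table["snow"] = 2.0  # constant column collinear with intercept
        with pytest.raises(ValueError, match="collinear"):
            fit(SNOW_ONLY, table)

    def test_aicc_formula(self):
        rng = np.random.default_rng(9)
        table = _toy_table(200, rng)
        f = fit(SNOW_ONLY, table)
        k, n = f.k, f.n
        assert f.aicc == pytest.approx(
            -2 * f.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        )


class TestAiccCompare:
    @staticmethod
    def _fake(name, loglik, k, n=100):
        spec = ModelSpec(
            outcome="parturition",
            age_spec=DEFAULT_AGE_CLASSES,
            terms=("snow",),
            random="none",
            name=name,
        )
        f = FittedModel.from_coefficients(spec, {"Intercept": 0.0})
        f.loglik, f.k, f.n = loglik, k, n
        f.aicc = -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        return f

    def test_equal_aicc_gives_equal_weights(self):
        sel = aicc_compare([self._fake("a", -50, 2), self._fake("b", -50, 2)]).table
        assert np.allclose(sel["weight"], 0.5)

    def test_delta_two(self):
        sel = aicc_compare([self._fake("a", -50, 2), self._fake("b", -51, 2)]).table
        w = np.exp(-1) / (1 + np.exp(-1))
        assert sel["weight"].iloc[0] == pytest.approx(1 - w)
        assert sel["weight"].iloc[1] == pytest.approx(w)

    def test_single_model_weight_one(self):
        sel = aicc_compare([self._fake("a", -50, 2)]).table
        assert sel["weight"].iloc[0] == pytest.approx(1.0)

    def test_weights_invariant_to_loglik_shift(self):
        fits = [self._fake("a", -50, 2), self._fake("b", -53, 3), self._fake("c", -49, 4)]
        shifted = [self._fake(f.spec.name, f.loglik + 7.5, f.k) for f in fits]
        w1 = aicc_compare(fits).table.set_index("model")["weight"]
        w2 = aicc_compare(shifted).table.set_index("model")["weight"]
        pd.testing.assert_series_equal(w1, w2)

    def test_fewest_parameters_ranks_first_on_ties(self):
        sel = aicc_compare([self._fake("big", -50, 5), self._fake("small", -50, 2)]).table
        assert sel.iloc[0]["model"] == "small"

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError, match="observation"):
            aicc_compare([self._fake("a", -50, 2, n=100), self._fake("b", -50, 2, n=90)])


class TestAuc:
    def test_perfect_separation(self):
        assert auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties_is_half(self):
        assert auc(np.full(10, 0.5), np.array([1, 0] * 5)) == 0.5

    def test_toy_enumeration(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4])
        y = np.array([1, 1, 0, 1, 0])
        assert auc(scores, y) == pytest.approx(5 / 6)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores = rng.random(200).round(1)  # coarse scores force ties
        y = (rng.random(200) < scores).astype(int)
        assert auc(scores, y) == pytest.approx(roc_auc_score(y, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.1, 0.9]), np.array([1, 1]))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(12)
    table = _toy_table(400, rng)
    return fit(SNOW_ONLY, table), table


class TestDiagnostics:

    def test_deterministic_under_seed(self, fitted):
        f, table = fitted
        a = residual_diagnostics(f, table, n_sim=100, seed=42)
        b = residual_diagnostics(f, table, n_sim=100, seed=42)
        assert a.ks_p == b.ks_p and a.dispersion_ratio == b.dispersion_ratio

    def test_self_consistency_under_the_null(self, fitted):
        f, table = fitted
        rep = residual_diagnostics(f, table, n_sim=300, seed=1)
        assert 0.8 < rep.dispersion_ratio < 1.2
        assert rep.ks_p > 0.01

    def test_overdispersion_detected(self):
        # individuals belong to latent groups at p=0.05 and p=0.95 but are
        # fitted as one homogeneous model with no random effect: the
        # variance of within-individual outcome sums then exceeds what the
        # fitted independent-Bernoulli model can produce
        rng = np.random.default_rng(13)
        n_ind, per = 60, 10
        latent = rng.random(n_ind) < 0.5
        p_ind = np.where(latent, 0.95, 0.05)
        gi = np.repeat(np.arange(n_ind), per)
        table = pd.DataFrame(
            {
                "y": (rng.random(n_ind * per) < p_ind[gi]).astype(int),
                "snow": rng.uniform(0, 3, n_ind * per),  # uninformative
                "individual_id": [f"i{g}" for g in gi],
                "site": "s1",
            }
        )
        f = fit(SNOW_ONLY, table)
        rep = residual_diagnostics(f, table, n_sim=200, seed=2)
        assert rep.dispersion_ratio > 1.5
        assert rep.dispersion_p < 0.05

    def test_small_n_sim_rejected(self, fitted):
        f, table = fitted
        with pytest.raises(ValueError):
            residual_diagnostics(f, table, n_sim=1)


class TestRandomEffects:
    def test_individual_variance_detected(self):
        rng = np.random.default_rng(14)
        n_ind, per = 60, 20
        gi = np.repeat(np.arange(n_ind), per)
        u = rng.normal(0, 1.0, n_ind)
        snow = rng.uniform(0, 3, n_ind * per)
        p = expit(0.5 - 0.5 * snow + u[gi])
        table = pd.DataFrame(
            {
                "y": (rng.random(len(p)) < p).astype(int),
                "snow": snow,
                "individual_id": [f"i{g}" for g in gi],
                "site": ["s1" if g % 2 else "s2" for g in gi],
            }
        )
        res = assess_random_effects(SNOW_ONLY, table)
        best = res.selection.table.iloc[0]["model"]
        assert "individual" in best
        assert res.lrt_p["individual"] < 1e-4
        f_ind = res.fits["individual"]
        assert 0.6 < f_ind.sigma_u < 1.5

    def test_no_variance_prefers_fixed_only(self):
        rng = np.random.default_rng(15)
        table = _toy_table(600, rng)
        table["individual_id"] = [f"i{k % 60}" for k in range(600)]
        res = assess_random_effects(SNOW_ONLY, table)
        sel = res.selection.table.set_index("model")
        # fixed-only model is within 2 AICc of the best variant
        assert sel.loc["parturition | none", "delta"] < 2.0


def test_matches_lme4_on_shared_fixture(tmp_path, parturition_table):
    """Independent oracle: lme4's adaptive quadrature fit on the same data."""
    table = parturition_table
    csv = tmp_path / "tab.csv"
    table.to_csv(csv, index=False)
    rscript = textwrap.dedent(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$ac <- relevel(factor(d$age_class), ref="3")
        d$prime <- as.integer(d$age_class == "6-10")
        m <- glmer(y ~ ac + prev_reproduction + snow + temp +
                       prev_reproduction:prime + (1 | individual_id),
                   data = d, family = binomial, nAGQ = 21)
        cat(as.numeric(logLik(m)), fixef(m)[["snow"]],
            fixef(m)[["prev_reproduction"]], sqrt(unlist(VarCorr(m))), sep=",")
        """
    )
    rfile = tmp_path / "check.R"
    rfile.write_text(rscript)
    proc = subprocess.run(
        ["Rscript", str(rfile)], capture_output=True, text=True, timeout=300
    )
    if proc.returncode != 0:
        pytest.skip(f"Rscript unavailable or failed: {proc.stderr[-200:]}")
    ll, snow, prev, sigma = map(float, proc.stdout.strip().split(",")[-4:])
    f = fit(PARTURITION_SPEC, table)
    # our optimum must be at least as good, and estimates must agree
    assert f.loglik >= ll - 1e-3
    assert f.params["snow"] == pytest.approx(snow, abs=0.02)
    assert f.params["prev_repro"] == pytest.approx(prev, abs=0.05)
    assert f.sigma_u == pytest.approx(sigma, abs=0.08)
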