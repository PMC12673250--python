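"""Binary-outcome logistic models with optional random intercepts.

Maximum-likelihood fitting of fixed-effect and random-intercept logistic
regressions, AICc-based model comparison with Akaike weights,
likelihood-ratio assessment of variance components, ROC/AUC discrimination,
and simulation-based residual diagnostics.

The random-intercept marginal likelihood integrates each group's Bernoulli
product over a Gaussian intercept u ~ N(0, sigma_u^2).  The integral is
evaluated by Gauss-Hermite quadrature::

    L_g = (1/sqrt(pi)) * sum_k w_k * prod_t Bernoulli(y_gt | expit(x_gt b + sqrt(2) sigma z_k))

with (z_k, w_k) the physicists' Hermite nodes/weights (default 21 nodes).
Analytic gradients of the quadrature log-likelihood drive a quasi-Newton
optimizer; the coefficient covariance is the inverse negative Hessian
obtained by finite differences of that gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .data_model import AgeClassSpec

__all__ = [
    "ModelSpec",
    "FittedModel",
    "SelectionTable",
    "design_matrix",
    "log_likelihood",
    "fit",
    "aicc_compare",
    "auc",
    "residual_diagnostics",
    "assess_random_effects",
    "simulate_outcomes",
]

RANDOM_STRUCTURES = ("none", "individual", "site", "individual_in_site")

#: |beta| beyond which a coefficient is treated as evidence of separation.
SEPARATION_THRESHOLD = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """Design definition for one candidate model.

    ``terms`` draws from: ``"age"`` (dummy per non-reference bin of
    ``age_spec``), ``"prev_repro"``, ``"snow"``, ``"temp"``, and interaction
    tokens of the form ``"prev_repro:age[LABEL]"``.
    """

    outcome: str
    age_spec: AgeClassSpec
    terms: tuple[str, ...]
    random: str = "individual"
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.random not in RANDOM_STRUCTURES:
            raise ValueError(f"unknown random structure {self.random!r}")
        mains = set(self.terms)
        for t in self.terms:
            if t.startswith("prev_repro:age["):
                label = t[len("prev_repro:age[") : -1]
                if "prev_repro" not in mains:
                    raise ValueError(f"interaction {t!r} lacks main effect prev_repro")
                if "age" not in mains:
                    raise ValueError(f"interaction {t!r} lacks main effect age")
                if label not in self.age_spec.labels:
                    raise ValueError(f"interaction {t!r} references unknown age class")
            elif t not in ("age", "prev_repro", "snow", "temp"):
                raise ValueError(f"unknown term {t!r}")

    @property
    def label(self) -> str:
        return self.name or " + ".join(self.terms) + f" | {self.random}"


def design_matrix(spec: ModelSpec, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Build the fixed-effects design matrix for an analysis table.

    The table must carry ``age_class`` (labels from ``spec.age_spec``) and
    whichever of ``prev_reproduction``, ``snow``, ``temp`` the terms need.
    The reference age class carries no dummy.
    """
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["Intercept"]
    if "age" in spec.terms:
        ac = table["age_class"].to_numpy()
        for label in spec.age_spec.labels[1:]:
            cols.append((ac == label).astype(float))
            names.append(f"age[{label}]")
    if "prev_repro" in spec.terms:
        cols.append(table["prev_reproduction"].to_numpy(dtype=float))
        names.append("prev_repro")
    if "snow" in spec.terms:
        cols.append(table["snow"].to_numpy(dtype=float))
        names.append("snow")
    if "temp" in spec.terms:
        cols.append(table["temp"].to_numpy(dtype=float))
        names.append("temp")
    for t in spec.terms:
        if t.startswith("prev_repro:age["):
            label = t[len("prev_repro:age[") : -1]
            prev = table["prev_reproduction"].to_numpy(dtype=float)
            ind = (table["age_class"].to_numpy() == label).astype(float)
            cols.append(prev * ind)
            names.append(t)
    return np.column_stack(cols), names


def group_codes(spec: ModelSpec, table: pd.DataFrame) -> Optional[np.ndarray]:
    """Integer group index per row for the spec's random structure.

    ``individual_in_site`` reduces to individual-level grouping because each
    individual occurs in exactly one site; the nesting changes nothing once
    individuals are uniquely identified.
    """
    if spec.random == "none":
        return None
    if spec.random == "site":
        key = table["site"].astype(str)
    else:
        key = table["individual_id"].astype(str)
    return pd.factorize(key)[0]


# ---------------------------------------------------------------------------
# Likelihood machinery


def _gh(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    return z, np.log(w) - 0.5 * np.log(np.pi)


def _bernoulli_loglik_matrix(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log Bernoulli(y | expit(eta)) for eta of shape (n, K), y of shape (n,)."""
    # log expit(eta) = -log1p(exp(-eta)), numerically stable via logaddexp
    s = np.where(y[:, None] == 1, eta, -eta)
    return -np.logaddexp(0.0, -s)


def _nll_and_grad(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    group_idx: Optional[np.ndarray],
    starts: Optional[np.ndarray],
    z: np.ndarray,
    logw: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient.

    With a random term, ``theta = (beta, sigma_u)`` and rows must be sorted
    by group with ``starts`` the reduceat boundaries.
    """
    if group_idx is None:
        beta = theta
        eta = X @ beta
        p = expit(eta)
        ll = float(np.sum(np.where(y == 1, -np.logaddexp(0, -eta), -np.logaddexp(0, eta))))
        grad = X.T @ (y - p)
        return -ll, -grad

    beta, sigma = theta[:-1], theta[-1]
    eta = (X @ beta)[:, None] + np.sqrt(2.0) * sigma * z[None, :]  # (n, K)
    L = _bernoulli_loglik_matrix(eta, y)  # (n, K)
    A = np.add.reduceat(L, starts, axis=0)  # (G, K) within-group sums
    B = A + logw[None, :]
    lse = logsumexp(B, axis=1)  # (G,)
    ll = float(lse.sum())

    # posterior node weights per group, expanded to rows
    R = np.exp(B - lse[:, None])  # (G, K)
    counts = np.diff(np.append(starts, len(y)))
    R_rows = np.repeat(R, counts, axis=0)  # (n, K)
    resid = y[:, None] - expit(eta)  # (n, K)
    W = R_rows * resid
    grad_beta = X.T @ W.sum(axis=1)
    grad_sigma = np.sqrt(2.0) * float((W @ z).sum())
    grad = np.append(grad_beta, grad_sigma)
    return -ll, -grad


def _prepare(X, y, group_idx):
    """Sort rows by group and compute reduceat starts."""
    order = np.argsort(group_idx, kind="stable")
    g = group_idx[order]
    starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
    return X[order], y[order], starts


def log_likelihood(
    beta: np.ndarray,
    sigma_u: float,
    X: np.ndarray,
    y: np.ndarray,
    group_idx: Optional[np.ndarray] = None,
    n_nodes: int = 21,
) -> float:
    """Marginal log-likelihood of a (possibly random-intercept) logistic model.

    With ``group_idx`` given, each group's Bernoulli product is integrated
    over u ~ N(0, sigma_u^2) by Gauss-Hermite quadrature with ``n_nodes``
    nodes; ``sigma_u = 0`` degenerates exactly to the fixed-effects value.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)) or not np.isfinite(sigma_u):
        raise ValueError("non-finite parameters")
    if sigma_u < 0:
        raise ValueError("sigma_u must be >= 0")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if group_idx is None or sigma_u == 0.0:
        eta = X @ beta
        return float(
            np.sum(np.where(y == 1, -np.logaddexp(0, -eta), -np.logaddexp(0, eta)))
        )
    z, logw = _gh(n_nodes)
    Xs, ys, starts = _prepare(X, y, np.asarray(group_idx))
    nll, _ = _nll_and_grad(
        np.append(beta, sigma_u), Xs, ys, np.asarray(group_idx), starts, z, logw
    )
    return -nll


@dataclass
class FittedModel:
    """A fitted (or externally supplied) logistic model.

    ``params`` maps term name to estimate; ``cov`` is the coefficient
    covariance (including sigma_u last when estimated); ``sigma_u`` is the
    random-intercept SD (0 for fixed-effects-only models).
    """

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    sigma_u: float
    loglik: float
    n: int
    k: int
    aicc: float
    converged: bool
    separation: bool = False
    n_groups: int = 0

    @property
    def se(self) -> pd.Series:
        names = list(self.params.index)
        if self.sigma_u > 0 and "sigma_u" in self.cov.index:
            names = names
        d = np.sqrt(np.clip(np.diag(self.cov.loc[names, names].to_numpy()), 0, None))
        return pd.Series(d, index=names)

    def coefficient_table(self) -> pd.DataFrame:
        """Estimate, SE, Wald 95% CI, Z and p per fixed-effect term."""
        se = self.se
        est = self.params
        z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "term": est.index,
                "estimate": est.to_numpy(),
                "SE": se.to_numpy(),
                "CI_low": est.to_numpy() - 1.96 * se.to_numpy(),
                "CI_high": est.to_numpy() + 1.96 * se.to_numpy(),
                "Z": z.to_numpy(),
                "p": p,
            }
        )

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        X, names = design_matrix(self.spec, table)
        return X @ self.params.reindex(names).to_numpy()

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Typical-individual (random effect at zero) probabilities."""
        return expit(self.linear_predictor(table))

    @classmethod
    def from_coefficients(
        cls,
        spec: ModelSpec,
        params: Mapping[str, float],
        se: Optional[Mapping[str, float]] = None,
        sigma_u: float = 0.0,
    ) -> "FittedModel":
        """Wrap an externally supplied coefficient table (no fit statistics)."""
        s = pd.Series(dict(params), dtype=float)
        if se is None:
            cov = pd.DataFrame(np.zeros((len(s), len(s))), index=s.index, columns=s.index)
        else:
            d = np.array([se[k] for k in s.index], dtype=float)
            cov = pd.DataFrame(np.diag(d**2), index=s.index, columns=s.index)
        return cls(
            spec=spec,
            params=s,
            cov=cov,
            sigma_u=sigma_u,
            loglik=np.nan,
            n=0,
            k=len(s) + (1 if sigma_u > 0 else 0),
            aicc=np.nan,
            converged=True,
        )


def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad or names}")


def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    init: Optional[np.ndarray] = None,
    n_nodes: int = 21,
) -> FittedModel:
    """Maximum-likelihood fit of a ModelSpec to an analysis table.

    The table needs columns ``y``, ``age_class``, ``individual_id``,
    ``site`` and the covariates the terms reference.  Optimization is
    L-BFGS-B on the analytic-gradient negative log-likelihood, starting at
    beta = 0, sigma_u = 0.3, with a restart grid on sigma_u if the first
    attempt fails to converge.  The covariance is the inverse negative
    Hessian (central finite differences of the gradient).
    """
    y = data["y"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    X, names = design_matrix(spec, data)
    _check_rank(X, names)
    gi = group_codes(spec, data)
    z, logw = _gh(n_nodes)

    p_fix = X.shape[1]
    has_re = gi is not None
    if has_re:
        Xs, ys, starts = _prepare(X, y, gi)
        n_groups = len(starts)
    else:
        Xs, ys, starts, n_groups = X, y, None, 0

    def objective(theta):
        return _nll_and_grad(theta, Xs, ys, gi if has_re else None, starts, z, logw)

    def run(start_sigma):
        theta0 = np.zeros(p_fix + (1 if has_re else 0))
        if init is not None:
            theta0[: len(init)] = init
        if has_re:
            theta0[-1] = start_sigma
        bounds = [(None, None)] * p_fix + ([(0.0, None)] if has_re else [])
        return optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )

    sigma_starts = [0.3, 0.05, 1.0] if has_re else [0.0]
    res = None
    for s0 in sigma_starts:
        res = run(s0)
        grad_norm = float(np.max(np.abs(res.jac)))
        if res.success and grad_norm < 1e-3:
            break
    theta = res.x
    loglik = -float(res.fun)
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success and grad_norm < 1e-2)

    beta = theta[:p_fix]
    sigma_u = float(theta[-1]) if has_re else 0.0
    separation = bool(np.any(np.abs(beta) > SEPARATION_THRESHOLD))
    if separation:
        warnings.warn("possible complete separation: |beta| > 15", stacklevel=2)

    # Hessian by central differences of the analytic gradient
    dim = len(theta)
    H = np.zeros((dim, dim))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(dim):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        if has_re:
            tp[-1] = max(tp[-1], 0.0)
            tm[-1] = max(tm[-1], 0.0)
        _, gp = objective(tp)
        _, gm = objective(tm)
        H[:, j] = (gp - gm) / (tp[j] - tm[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    cov_names = names + (["sigma_u"] if has_re else [])
    cov_df = pd.DataFrame(cov, index=cov_names, columns=cov_names)

    k = p_fix + (1 if has_re else 0)
    n = len(y)
    return FittedModel(
        spec=spec,
        params=pd.Series(beta, index=names),
        cov=cov_df,
        sigma_u=sigma_u,
        loglik=loglik,
        n=n,
        k=k,
        aicc=_aicc(loglik, k, n),
        converged=converged,
        separation=separation,
        n_groups=n_groups,
    )


# ---------------------------------------------------------------------------
# Model comparison


@dataclass
class SelectionTable:
    """AICc ranking of candidate fits, with Akaike weights."""

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def aicc_compare(fits: Sequence[FittedModel]) -> SelectionTable:
    """Rank candidate fits by AICc; weights w_i = exp(-delta_i/2), normalized.

    All fits must be on identical observation sets (same n); comparing
    AICc across different data is meaningless.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits on different observation counts: {sorted(ns)}")
    rows = pd.DataFrame(
        {
            "model": [f.spec.label for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "AICc": [f.aicc for f in fits],
        }
    )
    rows["delta"] = rows["AICc"] - rows["AICc"].min()
    rel = np.exp(-rows["delta"] / 2)
    rows["weight"] = rel / rel.sum()
    rows = rows.sort_values(["AICc", "k"], kind="stable").reset_index(drop=True)
    return SelectionTable(rows)


def auc(fit_or_scores, data: Optional[pd.DataFrame] = None) -> float:
    """Rank-statistic area under the ROC curve (ties count half).

    Accepts either a FittedModel plus analysis table (scores are the
    typical-individual predicted probabilities) or a precomputed score
    array with ``data`` a 0/1 outcome array.
    """
    if isinstance(fit_or_scores, FittedModel):
        scores = fit_or_scores.predict(data)
        y = data["y"].to_numpy(dtype=int)
    else:
        scores = np.asarray(fit_or_scores, dtype=float)
        y = np.asarray(data, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both outcome classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


AUC_BANDS = (
    (0.8, "excellent"),
    (0.7, "acceptable"),
    (0.5, "low"),
    (-np.inf, "poor"),
)


def auc_band(value: float) -> str:
    for lo, label in AUC_BANDS:
        if value > lo:
            return label
    return "poor"


# ---------------------------------------------------------------------------
# Diagnostics


def simulate_outcomes(
    fit: FittedModel, data: pd.DataFrame, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n_sim replicate outcome vectors from the fitted model.

    Random intercepts are redrawn per group and replicate, so the
    replicates carry the model's full marginal variability.
    """
    eta = fit.linear_predictor(data)
    n = len(eta)
    gi = group_codes(fit.spec, data)
    if gi is None or fit.sigma_u == 0:
        p = expit(np.broadcast_to(eta, (n_sim, n)))
    else:
        n_groups = gi.max() + 1
        u = rng.normal(0.0, fit.sigma_u, size=(n_sim, n_groups))
        p = expit(eta[None, :] + u[:, gi])
    return (rng.random((n_sim, n)) < p).astype(int)


@dataclass
class DiagnosticsReport:
    ks_statistic: float
    ks_p: float
    dispersion_ratio: float
    dispersion_p: float
    residuals: np.ndarray
    n_sim: int


def residual_diagnostics(
    fit: FittedModel, data: pd.DataFrame, n_sim: int = 250, seed: int = 0
) -> DiagnosticsReport:
    """Simulation-based residual diagnostics for a binary-outcome fit.

    Randomized-quantile (scaled) residuals place each observation within
    its simulated reference distribution: r_i = P(sim_i < y_i) + U * P(sim_i
    = y_i).  Under a correct model these are uniform; a K-S test quantifies
    departure.  The dispersion statistic is a Pearson chi-square of
    individual-level outcome sums against their fitted expectations
    (per-observation Pearson residuals carry no dispersion information for
    strictly binary data, but unmodelled heterogeneity inflates the
    variance of within-individual sums); the ratio compares the observed
    statistic with the mean of its simulated distribution, and its p-value
    is the two-sided simulation p-value.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    rng = np.random.default_rng(seed)
    y = data["y"].to_numpy(dtype=int)
    sims = simulate_outcomes(fit, data, n_sim, rng)  # (n_sim, n)

    p_lower = (sims < y[None, :]).mean(axis=0)
    p_equal = (sims == y[None, :]).mean(axis=0)
    resid = p_lower + rng.random(len(y)) * p_equal
    ks_stat, ks_p = stats.kstest(resid, "uniform")

    p_hat = fit.predict(data)
    if "individual_id" in data.columns:
        gi = pd.factorize(data["individual_id"].astype(str))[0]
    else:
        gi = np.arange(len(y))
    n_cl = gi.max() + 1
    E = np.bincount(gi, weights=p_hat, minlength=n_cl)
    V = np.clip(np.bincount(gi, weights=p_hat * (1 - p_hat), minlength=n_cl), 1e-12, None)

    def _chi(mat: np.ndarray) -> np.ndarray:
        S = np.apply_along_axis(
            lambda row: np.bincount(gi, weights=row, minlength=n_cl), 1, mat
        )
        return np.sum((S - E[None, :]) ** 2 / V[None, :], axis=1)

    chi_obs = float(_chi(y[None, :])[0])
    chi_sim = _chi(sims)
    ratio = chi_obs / float(np.mean(chi_sim))
    p_hi = (np.sum(chi_sim >= chi_obs) + 1) / (n_sim + 1)
    p_lo = (np.sum(chi_sim <= chi_obs) + 1) / (n_sim + 1)
    disp_p = min(1.0, 2 * min(p_hi, p_lo))
    return DiagnosticsReport(
        ks_statistic=float(ks_stat),
        ks_p=float(ks_p),
        dispersion_ratio=float(ratio),
        dispersion_p=float(disp_p),
        residuals=resid,
        n_sim=n_sim,
    )


# ---------------------------------------------------------------------------
# Random-effect assessment


@dataclass
class RandomEffectAssessment:
    selection: SelectionTable
    fits: dict[str, FittedModel]
    lrt_p: dict[str, float]
    errors: dict[str, str]


def assess_random_effects(
    base_spec: ModelSpec, data: pd.DataFrame, n_nodes: int = 21
) -> RandomEffectAssessment:
    """Contrast the fixed-effects-only model against each random-intercept variant.

    Fits the same fixed structure with random = none / individual / site /
    individual_in_site, ranks them by AICc, and reports the boundary-
    corrected likelihood-ratio p-value of each variance component against
    the fixed-only null (50:50 mixture of chi2_0 and chi2_1, i.e.
    p = 0.5 * P(chi2_1 > D)).
    """
    fits: dict[str, FittedModel] = {}
    errors: dict[str, str] = {}
    for structure in RANDOM_STRUCTURES:
        spec = replace(base_spec, random=structure, name=f"{base_spec.outcome} | {structure}")
        try:
            fits[structure] = fit(spec, data, n_nodes=n_nodes)
        except Exception as exc:  # continue other variants per contract
            errors[structure] = str(exc)
    if "none" not in fits:
        raise RuntimeError(f"fixed-effects null failed: {errors.get('none')}")
    ll0 = fits["none"].loglik
    lrt_p = {}
    for structure, f in fits.items():
        if structure == "none":
            continue
        D = max(0.0, 2 * (f.loglik - ll0))
        lrt_p[structure] = float(0.5 * stats.chi2.sf(D, df=1)) if D > 0 else 1.0
    sel = aicc_compare(list(fits.values()))
    return RandomEffectAssessment(selection=sel, fits=fits, lrt_p=lrt_p, errors=errors)
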