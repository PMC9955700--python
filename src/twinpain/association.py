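"""Univariate and multivariable association tables with family clustering.

Offspring (twins plus first siblings) share family environment and genes, so
their analyses use a random-intercept logistic regression with one Gaussian
intercept per family; the marginal likelihood is maximized with adaptive
Gauss-Hermite quadrature (default 15 nodes, each cluster's integrand centered
at its posterior mode). Parents are analysed with ordinary logistic
regression. Offspring models always include age; sex is included only when
significant. Tables carry one univariate fit per predictor plus one joint
multivariable fit over all listed predictors, with a retained-significance
flag at p < 0.05; no multiple-testing correction is applied by default (an
optional Bonferroni switch is provided).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess1

from .datamodel import (
    CONDITIONS,
    REGIONS,
    Cohort,
    Role,
    Tristate,
    TwinpainError,
    map_sites_to_regions,
)
from .family import AssociationResult, _degenerate_result, _trait_num
from .similarity import Z95

logger = logging.getLogger("twinpain")

__all__ = [
    "MixedLogitFit",
    "AssociationTable",
    "fit_random_intercept_logit",
    "random_intercept_logit",
    "build_association_table",
    "expected_cross_trait_check",
    "REGION_PREDICTORS",
    "CONDITION_PREDICTORS",
]

_LOG_SIGMA_MIN = math.log(1e-4)
_LOG_SIGMA_MAX = math.log(10.0)


@dataclass
class MixedLogitFit:
    """Raw output of the adaptive-quadrature random-intercept logistic fit."""

    params: np.ndarray  # fixed-effect coefficients, intercept first
    cov: np.ndarray  # covariance of the fixed effects
    names: list[str]
    sigma: float  # random-intercept SD
    loglike: float
    converged: bool
    n_obs: int
    n_clusters: int
    note: str = ""

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        z = self.params / se
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
                "or": np.exp(self.params),
                "ci_low": np.exp(self.params - Z95 * se),
                "ci_high": np.exp(self.params + Z95 * se),
            },
            index=self.names,
        )


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fit_random_intercept_logit(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    n_quad: int = 15,
    tol: float = 1e-6,
    fix_sigma: float | None = None,
) -> MixedLogitFit:
    """Maximum-likelihood logistic regression with one Gaussian random
    intercept per cluster, by adaptive Gauss-Hermite quadrature.

    For each cluster the integrand (conditional likelihood times the normal
    density of the intercept) is centered at its mode, found by Newton steps,
    and scaled by the local curvature before applying the quadrature rule —
    the standard adaptive scheme. The marginal log likelihood is maximized
    over the fixed effects and log(sigma) with L-BFGS-B (tolerance ``tol`` on
    the log likelihood); Wald covariance comes from the numerical Hessian at
    the optimum.

    ``X`` must already contain an intercept column (first). ``fix_sigma``
    holds the random-intercept SD constant instead of estimating it; at 0 the
    model reduces exactly to ordinary logistic regression.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    m = codes.max() + 1
    n, p = X.shape

    if fix_sigma is not None and fix_sigma < 1e-6:
        # degenerate limit: no cluster heterogeneity
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return MixedLogitFit(
            params=np.asarray(fit.params, dtype=float),
            cov=np.asarray(fit.cov_params(), dtype=float),
            names=names or [f"x{i}" for i in range(p)],
            sigma=0.0,
            loglike=float(fit.llf),
            converged=bool(fit.mle_retvals.get("converged", True)),
            n_obs=n,
            n_clusters=m,
        )

    nodes, weights = hermgauss(n_quad)
    log_weights = np.log(weights)
    estimate_sigma = fix_sigma is None

    def cluster_loglike(theta: np.ndarray) -> np.ndarray:
        beta = theta[:p]
        sigma = math.exp(theta[p]) if estimate_sigma else float(fix_sigma)
        eta = X @ beta
        # Newton search for each cluster's posterior mode of the intercept u
        u = np.zeros(m)
        for _ in range(50):
            pi = _expit(eta + u[codes])
            grad = np.bincount(codes, weights=y - pi, minlength=m) - u / sigma**2
            curv = np.bincount(codes, weights=pi * (1 - pi), minlength=m) + 1 / sigma**2
            step = grad / curv
            u += step
            if np.max(np.abs(step)) < 1e-9:
                break
        pi = _expit(eta + u[codes])
        curv = np.bincount(codes, weights=pi * (1 - pi), minlength=m) + 1 / sigma**2
        tau = 1.0 / np.sqrt(curv)  # per-cluster scale
        # evaluate log integrand at transformed nodes u_jk = u_j + sqrt(2) tau_j z_k
        u_nodes = u[:, None] + math.sqrt(2.0) * tau[:, None] * nodes[None, :]
        eta_nodes = eta[:, None] + u_nodes[codes]  # (n, K)
        # log conditional likelihood per observation and node
        ll_obs = y[:, None] * eta_nodes - np.logaddexp(0.0, eta_nodes)
        ll_cluster = np.zeros((m, n_quad))
        for k in range(n_quad):
            ll_cluster[:, k] = np.bincount(codes, weights=ll_obs[:, k], minlength=m)
        log_prior = (
            -0.5 * math.log(2 * math.pi) - math.log(sigma) - 0.5 * (u_nodes / sigma) ** 2
        )
        log_summand = log_weights[None, :] + nodes[None, :] ** 2 + ll_cluster + log_prior
        mx = log_summand.max(axis=1, keepdims=True)
        integral = np.exp(log_summand - mx).sum(axis=1)
        return (
            0.5 * math.log(2.0) + np.log(tau) + mx[:, 0] + np.log(integral)
        )

    def negloglike(theta: np.ndarray) -> float:
        return -float(cluster_loglike(theta).sum())

    # start at the ordinary-logit solution with a moderate sigma
    start = np.zeros(p + 1 if estimate_sigma else p)
    try:
        start[:p] = sm.Logit(y, X).fit(disp=0, maxiter=100).params
    except Exception:
        pass
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * p
    if estimate_sigma:
        start[p] = math.log(0.5)
        bounds.append((_LOG_SIGMA_MIN, _LOG_SIGMA_MAX))
    opt = minimize(
        negloglike, start, method="L-BFGS-B", bounds=bounds,
        options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
    )
    theta = opt.x
    note = "" if opt.success else f"optimizer: {opt.message}"
    # Wald covariance for the fixed effects from the observed information
    try:
        hess = approx_hess1(theta, negloglike)
        cov_all = np.linalg.inv(hess)
        cov = cov_all[:p, :p]
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        converged = opt.success
    except np.linalg.LinAlgError as exc:
        cov = np.full((p, p), np.nan)
        converged = False
        note = f"singular information matrix ({exc})"
    if np.any(np.abs(theta[:p]) > 15):
        converged = False
        note = note or "quasi-separation: unbounded estimate"
    return MixedLogitFit(
        params=theta[:p],
        cov=cov,
        names=names or [f"x{i}" for i in range(p)],
        sigma=math.exp(theta[p]) if estimate_sigma else float(fix_sigma),
        loglike=-opt.fun,
        converged=converged,
        n_obs=n,
        n_clusters=m,
        note=note,
    )


def _result_from_fit(
    fit: MixedLogitFit, outcome: str, predictor: str, covariates: tuple[str, ...]
) -> AssociationResult:
    if not fit.converged:
        return _degenerate_result(outcome, predictor, fit.n_obs, fit.note or
                                  "non-convergence", covariates,
                                  model="random_intercept_logit")
    tab = fit.coef_table()
    row = tab.loc[predictor]
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        odds_ratio=float(row["or"]),
        log_or_variance=float(row["se"] ** 2),
        ci_low=float(row["ci_low"]),
        ci_high=float(row["ci_high"]),
        p_value=float(row["p"]),
        n=fit.n_obs,
        covariates=covariates,
        model="random_intercept_logit",
    )


def random_intercept_logit(
    df: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    cluster: str = "family_id",
    covariates: tuple[str, ...] = ("age",),
    add_sex_if_significant: bool = True,
    n_quad: int = 15,
) -> dict[str, AssociationResult]:
    """Fit one clustered logistic model and return a result per predictor.

    ``df`` must hold numeric columns for the outcome, predictors, covariates
    and the cluster id; rows with missing values are dropped. Age is always
    included for offspring analyses; sex enters only if significant.
    """
    cols = [outcome, *predictors, *covariates, cluster]
    if add_sex_if_significant and "sex" in df.columns and "sex" not in cols:
        cols.append("sex")
    data = df[cols].dropna()
    n_dropped = len(df) - len(data)
    if n_dropped:
        logger.info("stage=random_intercept_logit outcome=%s dropped_missing=%d",
                    outcome, n_dropped)
    y = data[outcome].to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        return {
            pr: _degenerate_result(outcome, pr, len(y), "outcome has no variation",
                                   covariates, model="random_intercept_logit")
            for pr in predictors
        }

    def _fit(cov_list: tuple[str, ...]) -> MixedLogitFit:
        names = ["const", *predictors, *cov_list]
        X = np.column_stack(
            [np.ones(len(data))] + [data[c].to_numpy() for c in [*predictors, *cov_list]]
        )
        return fit_random_intercept_logit(
            y, X, data[cluster].to_numpy(), names=names, n_quad=n_quad
        )

    kept = tuple(covariates)
    if add_sex_if_significant and "sex" in data.columns:
        trial = _fit(kept + ("sex",))
        if trial.converged and trial.coef_table().loc["sex", "p"] < 0.05:
            kept = kept + ("sex",)
            fit = trial
        else:
            fit = _fit(kept)
    else:
        fit = _fit(kept)
    return {pr: _result_from_fit(fit, outcome, pr, kept) for pr in predictors}


def _ordinary_logit_results(
    df: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    covariates: tuple[str, ...] = (),
) -> dict[str, AssociationResult]:
    data = df[[outcome, *predictors, *covariates]].dropna()
    y = data[outcome].to_numpy()
    out: dict[str, AssociationResult] = {}
    if y.sum() == 0 or y.sum() == len(y):
        return {pr: _degenerate_result(outcome, pr, len(y),
                                       "outcome has no variation", covariates)
                for pr in predictors}
    X = sm.add_constant(data[[*predictors, *covariates]], has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        return {pr: _degenerate_result(outcome, pr, len(y), f"non-convergence: {exc}",
                                       covariates) for pr in predictors}
    for pr in predictors:
        beta, se = fit.params[pr], fit.bse[pr]
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15:
            out[pr] = _degenerate_result(outcome, pr, len(y),
                                         "quasi-separation: unbounded estimate",
                                         covariates)
            continue
        out[pr] = AssociationResult(
            outcome=outcome, predictor=pr, odds_ratio=math.exp(beta),
            log_or_variance=float(se**2), ci_low=math.exp(beta - Z95 * se),
            ci_high=math.exp(beta + Z95 * se), p_value=float(fit.pvalues[pr]),
            n=len(y), covariates=covariates, model="ordinary_logit",
        )
    return out


# --------------------------------------------------------------------------
# Association tables (regions or conditions as predictors)

REGION_PREDICTORS = {
    # outcome -> its own region(s), removed from the predictor list and from
    # the multiple-sites count
    "lbp_life": ("lower_back",),
    "tlbp_current": ("lower_back", "middle_back"),
}

CONDITION_PREDICTORS = list(CONDITIONS) + [
    "anxious_depression_score",
    "sensory_sensitivity_score",
]


@dataclass
class AssociationTable:
    """Univariate + multivariable association results for one outcome."""

    outcome: str
    population: str  # {twins_and_siblings, mothers, fathers}
    n_analysed: int
    rows: list[dict] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)  # predictor -> reason

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def cohort_frame(cohort: Cohort, population: str) -> pd.DataFrame:
    """Numeric analysis frame for one population, with region indicators."""
    roles = {
        "twins_and_siblings": (Role.TWIN1, Role.TWIN2, Role.FIRST_SIBLING),
        "mothers": (Role.MOTHER,),
        "fathers": (Role.FATHER,),
    }[population]
    rows = []
    for r in cohort.by_role(*roles):
        profile = map_sites_to_regions(r.pain_sites)
        row = {
            "family_id": r.family_id,
            "age": float("nan") if r.age is None else r.age,
            "sex": {"male": 0.0, "female": 1.0}.get(r.sex, float("nan")),
            "lbp_life": _trait_num(r, "lbp_life"),
            "tlbp_current": _trait_num(r, "tlbp_current"),
            "anxious_depression_score": (
                float("nan") if r.anxious_depression_score is None
                else float(r.anxious_depression_score)
            ),
            "sensory_sensitivity_score": (
                float("nan") if r.sensory_sensitivity_score is None
                else float(r.sensory_sensitivity_score)
            ),
        }
        for cond in CONDITIONS:
            row[cond] = _trait_num(r, cond)
        for region in REGIONS:
            row[f"region_{region}"] = float(profile[region])
        rows.append(row)
    columns = (
        ["family_id", "age", "sex", "lbp_life", "tlbp_current",
         "anxious_depression_score", "sensory_sensitivity_score"]
        + list(CONDITIONS)
        + [f"region_{r}" for r in REGIONS]
    )
    return pd.DataFrame(rows, columns=columns)


def _fit_population(
    df: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    population: str,
    n_quad: int = 15,
) -> dict[str, AssociationResult]:
    if population == "twins_and_siblings":
        return random_intercept_logit(df, outcome, predictors, covariates=("age",),
                                      n_quad=n_quad)
    # parents: ordinary logistic, unadjusted by default
    return _ordinary_logit_results(df, outcome, predictors)


def build_association_table(
    cohort: Cohort,
    outcome: str,
    predictor_set: str,
    population: str,
    min_cases: int = 10,
    bonferroni: bool = False,
    n_quad: int = 15,
) -> AssociationTable:
    """Univariate and joint multivariable association table for one outcome.

    ``predictor_set`` is ``"regions"`` (pain in other body regions plus a
    multiple-sites indicator, the outcome's own region(s) removed) or
    ``"conditions"`` (primary pain conditions, restless legs, iron-deficiency
    history, and the two continuous scores). Binary predictors with fewer than
    ``min_cases`` positives among analysed rows are dropped with a logged
    reason. Retention flags mark multivariate p < 0.05 (Bonferroni-adjusted if
    requested).
    """
    if outcome not in REGION_PREDICTORS:
        raise TwinpainError(f"unknown outcome: {outcome!r}")
    df = cohort_frame(cohort, population)
    own = REGION_PREDICTORS[outcome]

    if predictor_set == "regions":
        predictors = [f"region_{r}" for r in REGIONS if r not in own]
        non_outcome = [f"region_{r}" for r in REGIONS if r not in own]
        df = df.copy()
        df["multiple_sites"] = (df[non_outcome].sum(axis=1) >= 2).astype(float)
        predictors = ["multiple_sites"] + predictors
    elif predictor_set == "conditions":
        predictors = list(CONDITION_PREDICTORS)
    else:
        raise TwinpainError(f"unknown predictor set: {predictor_set!r}")

    analysed = df.dropna(subset=[outcome])
    dropped: dict[str, str] = {}
    usable = []
    for pr in predictors:
        col = analysed[pr].dropna()
        binary = set(col.unique()) <= {0.0, 1.0}
        if binary and col.sum() < min_cases:
            dropped[pr] = f"excluded because of low numbers ({int(col.sum())} cases)"
            continue
        if col.nunique() < 2:
            dropped[pr] = "constant predictor"
            continue
        usable.append(pr)
    for pr, reason in dropped.items():
        logger.info("stage=association outcome=%s predictor=%s dropped=%s",
                    outcome, pr, reason)
    if not usable:
        raise TwinpainError("all predictors dropped; empty association table")

    uni = {
        pr: _fit_population(df, outcome, [pr], population, n_quad=n_quad)[pr]
        for pr in usable
    }
    multi = _fit_population(df, outcome, usable, population, n_quad=n_quad)
    alpha = 0.05 / len(usable) if bonferroni else 0.05
    rows = []
    for pr in usable:
        u, m = uni[pr], multi[pr]
        rows.append(
            {
                "predictor": pr,
                "or_uni": u.odds_ratio,
                "ci_low_uni": u.ci_low,
                "ci_high_uni": u.ci_high,
                "p_uni": u.p_value,
                "or_multi": m.odds_ratio,
                "ci_low_multi": m.ci_low,
                "ci_high_multi": m.ci_high,
                "p_multi": m.p_value,
                "retained": bool(m.converged and m.p_value < alpha),
                "model": m.model,
            }
        )
    return AssociationTable(
        outcome=outcome,
        population=population,
        n_analysed=len(analysed),
        rows=rows,
        dropped=dropped,
    )


def expected_cross_trait_check(cohort: Cohort, n_quad: int = 15) -> dict[str, AssociationResult]:
    """Positive-control diagnostic: lifetime LBP predicting current TLBP.

    Age-adjusted random-intercept fit for the offspring, ordinary logistic
    regression for each parent. A strongly positive OR indicates the pipeline
    wiring (classification, clustering, model code) is intact.
    """
    out: dict[str, AssociationResult] = {}
    df = cohort_frame(cohort, "twins_and_siblings")
    out["twins_and_siblings"] = random_intercept_logit(
        df, "tlbp_current", ["lbp_life"], covariates=("age",), n_quad=n_quad
    )["lbp_life"]
    for pop in ("mothers", "fathers"):
        dfp = cohort_frame(cohort, pop)
        out[pop] = _ordinary_logit_results(dfp, "tlbp_current", ["lbp_life"])["lbp_life"]
    return out
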