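"""Family analysis: one random twin per pair, per-relative logistic fits,
inverse-variance combination.

One twin is drawn at random from each complete pair and the selected twins'
trait is regressed (ordinary logistic regression) on the same trait in a given
relative (co-twin, first sibling, mother, or father). The analysis is then
repeated with the non-selected co-twins as the index children, and the two
log odds ratios are combined by inverse-variance weighting, which uses all of
the twin information without double counting any family.

Covariates (age, sex) follow an adjust-if-significant policy: the model is
fitted with both, covariates with Wald p >= 0.05 are dropped, and the model is
refitted; the decision trail is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import Cohort, IndividualRecord, Role, Tristate, TwinpainError, Zygosity
from .similarity import Z95

logger = logging.getLogger("twinpain")

__all__ = [
    "AssociationResult",
    "select_random_twin",
    "relative_logit",
    "ivw_combine",
    "family_table",
    "RELATIVE_ROLES",
]

RELATIVE_ROLES = ("mz_cotwin", "dz_cotwin", "first_sibling", "mother", "father")


@dataclass(frozen=True)
class AssociationResult:
    """An odds ratio for predictor -> outcome with its CI, p, and provenance."""

    outcome: str
    predictor: str
    odds_ratio: float
    log_or_variance: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    covariates: tuple[str, ...] = ()
    model: str = "ordinary_logit"  # {ordinary_logit, random_intercept_logit, ivw_combined}
    converged: bool = True
    note: str = ""

    @property
    def log_or(self) -> float:
        return math.log(self.odds_ratio)


def _degenerate_result(outcome: str, predictor: str, n: int, note: str,
                       covariates: tuple[str, ...] = (),
                       model: str = "ordinary_logit") -> AssociationResult:
    return AssociationResult(
        outcome=outcome, predictor=predictor, odds_ratio=float("nan"),
        log_or_variance=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
        p_value=float("nan"), n=n, covariates=covariates, model=model,
        converged=False, note=note,
    )


def select_random_twin(
    pairs: list[tuple[IndividualRecord, IndividualRecord]],
    seed: int,
) -> tuple[list[IndividualRecord], list[IndividualRecord], dict[str, str]]:
    """Partition complete pairs into a selected twin and their co-twin.

    Reproducible given ``seed``; the returned dict logs which role was
    selected per family.
    """
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, 2, size=len(pairs))
    selected, cotwins, log = [], [], {}
    for (t1, t2), pick in zip(pairs, picks):
        chosen, other = (t1, t2) if pick == 0 else (t2, t1)
        selected.append(chosen)
        cotwins.append(other)
        log[chosen.family_id] = chosen.role.value
    return selected, cotwins, log


def _tri_to_num(value: Tristate) -> float:
    if value is Tristate.CASE:
        return 1.0
    if value is Tristate.CONTROL:
        return 0.0
    return float("nan")


def _trait_num(record: IndividualRecord, trait: str) -> float:
    v = getattr(record, trait)
    if trait == "lbp_life" and record.lbp_excluded:
        return float("nan")
    if trait == "tlbp_current" and record.tlbp_excluded:
        return float("nan")
    if isinstance(v, Tristate):
        return _tri_to_num(v)
    return float("nan") if v is None else float(v)


def _fit_logit(y: np.ndarray, X: pd.DataFrame, outcome: str, predictor: str,
               covariates: tuple[str, ...]) -> AssociationResult:
    n = len(y)
    if y.sum() == 0 or y.sum() == n:
        return _degenerate_result(outcome, predictor, n, "outcome has no variation",
                                  covariates)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation raises PerfectSeparationError
        return _degenerate_result(outcome, predictor, n, f"non-convergence: {exc}",
                                  covariates)
    beta = fit.params[predictor]
    se = fit.bse[predictor]
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15:
        return _degenerate_result(outcome, predictor, n,
                                  "quasi-separation: unbounded estimate", covariates)
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        odds_ratio=math.exp(beta),
        log_or_variance=se**2,
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        p_value=float(fit.pvalues[predictor]),
        n=n,
        covariates=covariates,
        model="ordinary_logit",
    )


def relative_logit(
    selected: list[IndividualRecord],
    cohort_or_relatives: Cohort | dict[str, IndividualRecord] | list[IndividualRecord],
    relative_role: str,
    trait: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    cotwins: list[IndividualRecord] | None = None,
) -> AssociationResult:
    """Ordinary logistic fit of the selected child's trait on a relative's trait.

    ``relative_role`` is one of ``mz_cotwin``/``dz_cotwin`` (requires
    ``cotwins`` aligned with ``selected``), ``first_sibling``, ``mother``,
    ``father``. Covariates with p >= 0.05 are dropped and the model refitted.
    """
    if relative_role not in RELATIVE_ROLES:
        raise TwinpainError(f"unknown relative role: {relative_role!r}")
    if relative_role.endswith("cotwin"):
        if cotwins is None:
            raise TwinpainError("co-twin analysis requires the cotwins arm")
        want = Zygosity.MZ if relative_role == "mz_cotwin" else Zygosity.DZ
        pairs = [
            (child, co) for child, co in zip(selected, cotwins)
            if child.zygosity is want
        ]
    else:
        if isinstance(cohort_or_relatives, Cohort):
            relatives = cohort_or_relatives.relatives(Role(relative_role))
        elif isinstance(cohort_or_relatives, dict):
            relatives = cohort_or_relatives
        else:
            relatives = {r.family_id: r for r in cohort_or_relatives
                         if r.role is Role(relative_role)}
        pairs = [
            (child, relatives[child.family_id]) for child in selected
            if child.family_id in relatives
        ]

    rows = []
    for child, rel in pairs:
        y = _trait_num(child, trait)
        x = _trait_num(rel, trait)
        row = {"y": y, trait: x}
        if "age" in covariates:
            row["age"] = float("nan") if child.age is None else child.age
        if "sex" in covariates:
            row["sex"] = {"male": 0.0, "female": 1.0}.get(child.sex, float("nan"))
        rows.append(row)
    df = pd.DataFrame(rows).dropna()
    if df.empty or df[trait].nunique() < 2:
        return _degenerate_result(trait, trait, len(df),
                                  "predictor constant or no usable pairs", covariates)

    kept = tuple(covariates)
    result = _fit_logit(df["y"].to_numpy(), df[[trait, *kept]], trait, trait, kept)
    # adjust-if-significant: refit without non-significant covariates
    if result.converged and kept:
        Xc = sm.add_constant(df[[trait, *kept]], has_constant="add")
        fit = sm.Logit(df["y"].to_numpy(), Xc).fit(disp=0, maxiter=200)
        keep = tuple(c for c in kept if fit.pvalues[c] < 0.05)
        if keep != kept:
            logger.info(
                "stage=relative_logit trait=%s relative=%s covariates_dropped=%s",
                trait, relative_role, sorted(set(kept) - set(keep)),
            )
            result = _fit_logit(df["y"].to_numpy(), df[[trait, *keep]], trait, trait,
                                keep)
    return replace(result, predictor=f"{relative_role}:{trait}")


def ivw_combine(first: AssociationResult, second: AssociationResult) -> AssociationResult:
    """Inverse-variance-weighted combination of two log odds ratios."""
    if (first.outcome, first.predictor) != (second.outcome, second.predictor):
        raise TwinpainError("cannot combine results for different outcome/predictor")
    for r in (first, second):
        if not r.converged or not np.isfinite(r.log_or_variance) or r.log_or_variance <= 0:
            raise TwinpainError("ivw_combine requires converged results with "
                                "positive finite variances")
    w1, w2 = 1 / first.log_or_variance, 1 / second.log_or_variance
    log_or = (w1 * first.log_or + w2 * second.log_or) / (w1 + w2)
    var = 1 / (w1 + w2)
    se = math.sqrt(var)
    z = log_or / se
    from scipy.stats import norm

    return AssociationResult(
        outcome=first.outcome,
        predictor=first.predictor,
        odds_ratio=math.exp(log_or),
        log_or_variance=var,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p_value=float(2 * norm.sf(abs(z))),
        n=first.n + second.n,
        covariates=tuple(sorted(set(first.covariates) | set(second.covariates))),
        model="ivw_combined",
    )


def family_table(
    cohort: Cohort,
    trait: str,
    seed: int,
    covariates: tuple[str, ...] = ("age", "sex"),
    combine_arms: bool = True,
) -> pd.DataFrame:
    """Per-relative association table for one trait (one row per relative).

    With ``combine_arms`` (default) each relative's estimate IVW-combines the
    two twin-selection arms (selected twins, then their co-twins); otherwise a
    single random arm is used.
    """
    pairs = cohort.twin_pairs()
    selected, cotwins, _ = select_random_twin(pairs, seed)
    rows = []
    for role in RELATIVE_ROLES:
        arm1 = relative_logit(selected, cohort, role, trait, covariates, cotwins=cotwins)
        result = arm1
        if combine_arms and not role.endswith("cotwin"):
            arm2 = relative_logit(cotwins, cohort, role, trait, covariates,
                                  cotwins=selected)
            if arm1.converged and arm2.converged:
                result = ivw_combine(arm1, arm2)
        rows.append(
            {
                "relative": role,
                "trait": trait,
                "n": result.n,
                "odds_ratio": result.odds_ratio,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "p_value": result.p_value,
                "model": result.model,
                "converged": result.converged,
                "note": result.note,
            }
        )
    return pd.DataFrame(rows)
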