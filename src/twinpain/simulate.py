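"""Synthetic twin-family cohorts under an ACE liability-threshold model.

Each binary trait arises when a latent standard-normal liability exceeds the
threshold implied by its prevalence. Liability is decomposed into additive
genetic (A), shared-environment (C) and unique (E) variance shares, giving the
classic familial correlations: a2 + c2 for MZ co-twins, a2/2 + c2 for DZ
co-twins and full siblings, a2/2 between parent and offspring (no assortative
mating). Cross-trait dependence uses a single shared "pain propensity" factor
(per-trait loading gamma, so trait s and t correlate gamma_s * gamma_t within
a person) plus optional planted pairwise correlations solved to hit a target
odds ratio. The full latent draw per family is multivariate normal with
covariance kron(R_family, C_traits).

Age raises prevalence through the liability: the thresholded score is
(L + beta * (age - role mean)) / sqrt(1 + beta^2 * sd_age^2), where
beta = log(OR per year) / 1.7 is the standard probit bridge of a logistic
slope. The normalization keeps the marginal prevalence at its target; because
twins share their exact age, a shared-age term beta^2 sd^2 / (1 + beta^2 sd^2)
adds to the effective co-twin liability correlation, and
:func:`theoretical_similarity` accounts for it. Parents get their own, higher
thresholds rather than an age extrapolation.

Defaults emulate the structure of a volunteer twin-family survey of pediatric
back pain: ~651 families (42% MZ), first sibling in ~65% and parents in
~87-98% of families, offspring lifetime-LBP prevalence 12.1% and current-TLBP
9.6%, parent prevalences 40-42% / 23-27%, offspring age effects OR 1.24/yr
(LBP) and 1.15/yr (TLBP), and a strong within-person LBP-TLBP association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .datamodel import (
    CONDITIONS,
    Cohort,
    IndividualRecord,
    Role,
    Tristate,
    TwinpainError,
    Zygosity,
)
from .similarity import DoubleEntryTable, PairCounts

logger = logging.getLogger("twinpain")

__all__ = [
    "ACEConfig",
    "ConfigError",
    "default_study_config",
    "simulate_cohort",
    "theoretical_similarity",
    "plant_cross_trait_effect",
    "TheoreticalSimilarity",
]


class ConfigError(TwinpainError):
    """Invalid or infeasible simulator configuration."""


PROBIT_LOGIT_BRIDGE = 1.7  # logistic slope ~= 1.7 * probit slope

BINARY_TRAITS = (
    "lbp_life",
    "tlbp_current",
    "region_lower_limbs",
    "region_upper_limbs",
    "region_chest",
    "region_abdomen",
    "region_head",
    "region_neck",
    "region_upper_back",
) + CONDITIONS

SCORE_TRAITS = ("anxious_depression", "sensory_sensitivity")
ALL_TRAITS = BINARY_TRAITS + SCORE_TRAITS

REGION_SITE = {
    "region_lower_limbs": "knees",
    "region_upper_limbs": "hands",
    "region_chest": "chest",
    "region_abdomen": "abdomen",
    "region_head": "head",
    "region_neck": "neck",
    "region_upper_back": "upper_back",
}

#: role -> (mean age, sd, min, max); sourced from the survey's summary margins
AGE_RANGES = {
    "twin": (15.3, 2.42, 6.0, 20.0),
    "first_sibling": (15.7, 4.61, 4.0, 36.0),
    "mother": (46.3, 4.93, 30.0, 64.0),
    "father": (48.7, 5.78, 35.0, 78.0),
}

_DEFAULT_PREVALENCE: dict[str, dict[str, float]] = {
    "lbp_life": {"offspring": 0.121, "mother": 0.420, "father": 0.399},
    "tlbp_current": {"offspring": 0.096, "mother": 0.266, "father": 0.231},
    "region_lower_limbs": {"offspring": 0.10, "mother": 0.18, "father": 0.15},
    "region_upper_limbs": {"offspring": 0.04, "mother": 0.10, "father": 0.08},
    "region_chest": {"offspring": 0.015, "mother": 0.02, "father": 0.02},
    "region_abdomen": {"offspring": 0.04, "mother": 0.04, "father": 0.03},
    "region_head": {"offspring": 0.05, "mother": 0.08, "father": 0.05},
    "region_neck": {"offspring": 0.08, "mother": 0.20, "father": 0.14},
    "region_upper_back": {"offspring": 0.04, "mother": 0.08, "father": 0.06},
    "migraine": {"offspring": 0.08, "mother": 0.18, "father": 0.08},
    "headache": {"offspring": 0.15, "mother": 0.20, "father": 0.15},
    "growing_pains": {"offspring": 0.15, "mother": 0.12, "father": 0.10},
    "recurrent_abdominal_pain": {"offspring": 0.12, "mother": 0.10, "father": 0.06},
    "chronic_pain_other": {"offspring": 0.05, "mother": 0.12, "father": 0.08},
    "restless_legs": {"offspring": 0.06, "mother": 0.12, "father": 0.10},
    "iron_deficiency_history": {"offspring": 0.08, "mother": 0.25, "father": 0.03},
}

_DEFAULT_LOADINGS: dict[str, float] = {
    **{t: 0.45 for t in BINARY_TRAITS},
    "iron_deficiency_history": 0.20,
    "anxious_depression": 0.30,
    "sensory_sensitivity": 0.30,
}

_DEFAULT_AGE_LOG_OR: dict[str, float] = {
    "lbp_life": math.log(1.24),
    "tlbp_current": math.log(1.15),
}

#: score trait -> (mean, sd, lo, hi) per role group
_SCORE_PARAMS = {
    ("anxious_depression", "offspring"): (6.0, 4.5, 0, 26),
    ("anxious_depression", "mother"): (8.0, 5.5, 0, 36),
    ("anxious_depression", "father"): (8.0, 5.5, 0, 36),
    ("sensory_sensitivity", "offspring"): (14.0, 5.0, 5, 35),
    ("sensory_sensitivity", "mother"): (14.0, 5.0, 5, 35),
    ("sensory_sensitivity", "father"): (14.0, 5.0, 5, 35),
}


@dataclass(frozen=True)
class ACEConfig:
    """Variance shares, margins, and effects for the cohort generator."""

    a2: float = 0.55
    c2: float = 0.10
    e2: float = 0.35
    n_families: int = 651
    mz_fraction: float = 0.422
    seed: int = 0
    sibling_rate: float = 0.645
    mother_rate: float = 0.983
    father_rate: float = 0.869
    prevalence: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PREVALENCE.items()}
    )
    age_log_or: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_LOG_OR)
    )
    factor_loadings: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOADINGS)
    )
    #: planted within-person trait-pair correlations overriding the factor product
    extra_corr: dict[frozenset, float] = field(default_factory=dict)
    minor_injury_rate: float = 0.32
    serious_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a2", "c2", "e2"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-9:
            raise ConfigError("a2 + c2 + e2 must equal 1")
        if not (0 < self.mz_fraction < 1):
            raise ConfigError("mz_fraction must lie in (0, 1)")
        for trait, by_role in self.prevalence.items():
            for role, q in by_role.items():
                if not (0 < q < 1):
                    raise ConfigError(f"prevalence of {trait}/{role} must be in (0,1)")
        # validate the trait correlation matrix up front
        self.trait_correlation()

    @property
    def mz_liability_correlation(self) -> float:
        return self.a2 + self.c2

    @property
    def dz_liability_correlation(self) -> float:
        return self.a2 / 2 + self.c2

    def trait_correlation(self) -> np.ndarray:
        """Within-person trait-liability correlation matrix (PSD-checked)."""
        g = np.array([self.factor_loadings.get(t, 0.0) for t in ALL_TRAITS])
        C = np.outer(g, g)
        np.fill_diagonal(C, 1.0)
        for pair, r in self.extra_corr.items():
            s, t = sorted(pair)
            i, j = ALL_TRAITS.index(s), ALL_TRAITS.index(t)
            C[i, j] = C[j, i] = r
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ConfigError("trait correlation matrix is not positive semi-definite")
        return C

    def family_correlation(self, zygosity: Zygosity) -> np.ndarray:
        """5x5 member correlation (twin1, twin2, sibling, mother, father)."""
        r_tw = (
            self.mz_liability_correlation
            if zygosity is Zygosity.MZ
            else self.dz_liability_correlation
        )
        r_sib = self.dz_liability_correlation
        r_po = self.a2 / 2
        R = np.eye(5)
        R[0, 1] = R[1, 0] = r_tw
        for off in (0, 1):
            R[off, 2] = R[2, off] = r_sib
            for par in (3, 4):
                R[off, par] = R[par, off] = r_po
        R[2, 3] = R[3, 2] = r_po
        R[2, 4] = R[4, 2] = r_po
        return R


def default_study_config(n_families: int = 651, seed: int = 0, **overrides) -> ACEConfig:
    """The study-conditions configuration, with the LBP-TLBP within-person
    correlation solved so the population cross-trait OR matches the published
    positive-control magnitude (17.7)."""
    cfg = ACEConfig(n_families=n_families, seed=seed, **overrides)
    return plant_cross_trait_effect(cfg, ("lbp_life", "tlbp_current"), 17.7)


# --------------------------------------------------------------------------
# Closed-form oracles


def _bvn_upper_orthant(t1: float, t2: float, r: float) -> float:
    """P(Z1 > t1, Z2 > t2) for standard bivariate normal with correlation r."""
    if r >= 1.0:  # comonotone limit
        return float(norm.sf(max(t1, t2)))
    if r <= -1.0:  # antithetic limit
        return float(max(0.0, norm.sf(t1) - norm.cdf(-t2)))
    return float(
        multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]).cdf([-t1, -t2])
    )


def _cells_from_corr(q1: float, q2: float, r: float) -> tuple[float, float, float, float]:
    t1, t2 = norm.isf(q1), norm.isf(q2)
    p11 = _bvn_upper_orthant(t1, t2, r)
    p10 = q1 - p11
    p01 = q2 - p11
    p00 = 1 - q1 - q2 + p11
    return p11, p10, p01, p00


@dataclass(frozen=True)
class TheoreticalSimilarity:
    concordance: float
    phi: float
    odds_ratio: float
    liability_correlation: float
    prevalence: float


def _effective_twin_correlation(config: ACEConfig, trait: str, zygosity: Zygosity) -> float:
    r = (
        config.mz_liability_correlation
        if zygosity is Zygosity.MZ
        else config.dz_liability_correlation
    )
    beta = config.age_log_or.get(trait, 0.0) / PROBIT_LOGIT_BRIDGE
    if beta:
        # co-twins share their exact age, which acts as extra shared variance
        sd = AGE_RANGES["twin"][1]
        shared = beta**2 * sd**2
        r = (r + shared) / (1 + shared)
    return r


def theoretical_similarity(
    config: ACEConfig, zygosity: Zygosity, trait: str = "lbp_life"
) -> TheoreticalSimilarity:
    """Expected pair similarity under the liability model, by bivariate-normal
    orthant integration (independent of the Monte-Carlo generator)."""
    q = config.prevalence[trait]["offspring"]
    r = _effective_twin_correlation(config, trait, zygosity)
    p11, p10, p01, p00 = _cells_from_corr(q, q, r)
    concordance = p11 / q
    phi = (p11 - q * q) / (q * (1 - q))
    if p10 <= 0 or p01 <= 0:
        odds_ratio = math.inf
    else:
        odds_ratio = p11 * p00 / (p10 * p01)
    return TheoreticalSimilarity(
        concordance=concordance,
        phi=phi,
        odds_ratio=odds_ratio,
        liability_correlation=r,
        prevalence=q,
    )


def plant_cross_trait_effect(
    config: ACEConfig, trait_pair: tuple[str, str], target_or: float
) -> ACEConfig:
    """Solve the within-person liability correlation of a trait pair so the
    population-level 2x2 odds ratio equals ``target_or`` (to 1e-3)."""
    if target_or <= 0:
        raise ConfigError("target odds ratio must be positive")
    ta, tb = trait_pair
    qa = config.prevalence[ta]["offspring"]
    qb = config.prevalence[tb]["offspring"]

    def log_or(r: float) -> float:
        p11, p10, p01, p00 = _cells_from_corr(qa, qb, r)
        if min(p11, p10, p01, p00) <= 0:
            return math.inf if r > 0 else -math.inf
        return math.log(p11 * p00 / (p10 * p01))

    target = math.log(target_or)
    lo, hi = -0.995, 0.995
    if not (log_or(lo) <= target <= log_or(hi)):
        raise ConfigError(
            f"target OR {target_or} unattainable for prevalences {qa}/{qb}"
        )
    r = 0.0 if target == 0 else brentq(lambda x: log_or(x) - target, lo, hi, xtol=1e-6)
    extra = dict(config.extra_corr)
    extra[frozenset(trait_pair)] = r
    new = replace(config, extra_corr=extra)
    logger.info("stage=plant_effect pair=%s target_or=%.4g solved_r=%.4f",
                trait_pair, target_or, r)
    return new


# --------------------------------------------------------------------------
# Cohort generation


def _draw_ages(rng: np.random.Generator, kind: str, n: int) -> np.ndarray:
    mean, sd, lo, hi = AGE_RANGES[kind]
    return np.clip(rng.normal(mean, sd, size=n), lo, hi)


def _threshold_score(
    liab: np.ndarray, ages: np.ndarray, kind: str, beta: float
) -> np.ndarray:
    """Combine liability and age effect, keeping the marginal standard normal."""
    if beta == 0.0:
        return liab
    mean, sd, _, _ = AGE_RANGES[kind]
    return (liab + beta * (ages - mean)) / math.sqrt(1 + beta**2 * sd**2)


def simulate_cohort(config: ACEConfig) -> Cohort:
    """Draw a twin-family cohort; deterministic given ``config.seed``.

    Emits records on the same schema that :func:`twinpain.datamodel.read_cohort`
    consumes: raw back-pain endorsements plus body-map sites (one
    representative site per painful region, a lower-back site when the TLBP
    liability is exceeded), condition indicators, and integer scale scores.
    """
    rng = np.random.default_rng(config.seed)
    n_fam = config.n_families
    n_mz = int(round(config.mz_fraction * n_fam))
    zygosities = [Zygosity.MZ] * n_mz + [Zygosity.DZ] * (n_fam - n_mz)

    T = len(ALL_TRAITS)
    C = config.trait_correlation()
    chol = {}
    for z in (Zygosity.MZ, Zygosity.DZ):
        cov = np.kron(config.family_correlation(z), C)
        # tiny jitter guards exact-singular limits (e.g. r = 1 for MZ)
        chol[z] = np.linalg.cholesky(cov + 1e-10 * np.eye(5 * T))

    Z = rng.standard_normal((n_fam, 5 * T))
    L = np.empty_like(Z)
    mz_mask = np.array([z is Zygosity.MZ for z in zygosities])
    L[mz_mask] = Z[mz_mask] @ chol[Zygosity.MZ].T
    L[~mz_mask] = Z[~mz_mask] @ chol[Zygosity.DZ].T
    L = L.reshape(n_fam, 5, T)  # member x trait

    twin_age = _draw_ages(rng, "twin", n_fam)
    sib_age = _draw_ages(rng, "first_sibling", n_fam)
    mother_age = _draw_ages(rng, "mother", n_fam)
    father_age = _draw_ages(rng, "father", n_fam)
    has_sib = rng.random(n_fam) < config.sibling_rate
    has_mother = rng.random(n_fam) < config.mother_rate
    has_father = rng.random(n_fam) < config.father_rate

    # sexes: MZ twins share sex, DZ twins independent
    twin1_sex = rng.random(n_fam) < 0.5
    twin2_sex = np.where(mz_mask, twin1_sex, rng.random(n_fam) < 0.5)
    sib_sex = rng.random(n_fam) < 0.5

    member_kinds = ("twin", "twin", "first_sibling", "mother", "father")
    member_ages = np.stack([twin_age, twin_age, sib_age, mother_age, father_age], axis=1)
    role_groups = ("offspring", "offspring", "offspring", "mother", "father")

    # binary trait matrix per member slot: (n_fam, 5, n_binary)
    binary = np.zeros((n_fam, 5, len(BINARY_TRAITS)), dtype=bool)
    for ti, trait in enumerate(BINARY_TRAITS):
        beta = config.age_log_or.get(trait, 0.0) / PROBIT_LOGIT_BRIDGE
        for mi, (kind, group) in enumerate(zip(member_kinds, role_groups)):
            q = config.prevalence[trait][group]
            t = norm.isf(q)
            b = beta if group == "offspring" else 0.0
            score = _threshold_score(L[:, mi, ti], member_ages[:, mi], kind, b)
            binary[:, mi, ti] = score > t

    score_latent = {
        trait: L[:, :, ALL_TRAITS.index(trait)] for trait in SCORE_TRAITS
    }
    injury = rng.random((n_fam, 5)) < config.minor_injury_rate
    serious = rng.random((n_fam, 5)) < config.serious_rate
    missing_lbp = rng.random((n_fam, 5)) < config.missing_rate
    missing_tlbp = rng.random((n_fam, 5)) < config.missing_rate

    trait_idx = {t: i for i, t in enumerate(BINARY_TRAITS)}
    records: list[IndividualRecord] = []
    roles = (Role.TWIN1, Role.TWIN2, Role.FIRST_SIBLING, Role.MOTHER, Role.FATHER)
    for f in range(n_fam):
        fid = f"F{f:05d}"
        present = (True, True, has_sib[f], has_mother[f], has_father[f])
        sexes = (
            "female" if twin1_sex[f] else "male",
            "female" if twin2_sex[f] else "male",
            "female" if sib_sex[f] else "male",
            "female",
            "male",
        )
        for mi, role in enumerate(roles):
            if not present[mi]:
                continue
            b = binary[f, mi]
            sites = {
                REGION_SITE[tr] for tr in REGION_SITE if b[trait_idx[tr]]
            }
            if b[trait_idx["tlbp_current"]]:
                sites.add("lower_back")
            group = role_groups[mi]

            def tri(flag: bool, missing: bool = False) -> Tristate:
                if missing:
                    return Tristate.MISSING
                return Tristate.CASE if flag else Tristate.CONTROL

            lbp_case = bool(b[trait_idx["lbp_life"]])
            scores = {}
            for st in SCORE_TRAITS:
                mean, sd, lo, hi = _SCORE_PARAMS[(st, group)]
                scores[st] = int(np.clip(round(mean + sd * score_latent[st][f, mi]), lo, hi))
            records.append(
                IndividualRecord(
                    family_id=fid,
                    role=role,
                    zygosity=zygosities[f] if role in (Role.TWIN1, Role.TWIN2)
                    else Zygosity.NOT_APPLICABLE,
                    age=round(float(member_ages[f, mi]), 1),
                    sex=sexes[mi],
                    pain_sites=frozenset(sites),
                    most_important_site=min(sites) if sites else None,
                    lbp_life=tri(lbp_case, missing_lbp[f, mi]),
                    tlbp_current=tri(bool(sites), missing_tlbp[f, mi]),
                    injury_flag=tri(lbp_case and injury[f, mi]),
                    serious_injury_or_disease=tri(serious[f, mi]),
                    migraine=tri(bool(b[trait_idx["migraine"]])),
                    headache=tri(bool(b[trait_idx["headache"]])),
                    growing_pains=tri(bool(b[trait_idx["growing_pains"]])),
                    recurrent_abdominal_pain=tri(
                        bool(b[trait_idx["recurrent_abdominal_pain"]])
                    ),
                    chronic_pain_other=tri(bool(b[trait_idx["chronic_pain_other"]])),
                    restless_legs=tri(bool(b[trait_idx["restless_legs"]])),
                    iron_deficiency_history=tri(
                        bool(b[trait_idx["iron_deficiency_history"]])
                    ),
                    anxious_depression_score=scores["anxious_depression"],
                    sensory_sensitivity_score=scores["sensory_sensitivity"],
                )
            )
    logger.info(
        "stage=simulate families=%d mz=%d records=%d seed=%d",
        n_fam, n_mz, len(records), config.seed,
    )
    return Cohort(records=records)
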