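"""Twin-pair similarity for binary traits: concordance, correlation, odds ratio.

The classic twin design infers genetic influence from monozygotic (MZ) pairs
being more alike than dizygotic (DZ) pairs. For a binary trait tallied over
complete pairs as (Nc, Nd, N00) = (both affected, exactly one affected,
neither affected), three similarity measures are computed:

* casewise concordance ``C = 2*Nc / (2*Nc + Nd)`` — the probability that the
  co-twin of an affected twin is affected, with variance
  ``4*Nc*Nd*(Nc+Nd) / (2*Nc+Nd)**4``;
* the phi correlation of the *double-entered* 2x2 table
  ``(a, b, c, d) = (2*Nc, Nd, Nd, 2*N00)`` (each pair entered twice, once per
  index twin), with a Fisher-z interval using n = number of pairs;
* the pairwise odds ratio ``a*d / (b*c) = 4*Nc*N00 / Nd**2`` with a Woolf
  (log-scale Wald) interval, variance ``1/a + 1/b + 1/c + 1/d``.

MZ-DZ differences are tested with a normal z statistic on each measure's
working scale (identity for C, Fisher z for the correlation, log for the OR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

from scipy.stats import norm

from .datamodel import Cohort, IndividualRecord, Role, Tristate, TwinpainError, Zygosity

logger = logging.getLogger("twinpain")

__all__ = [
    "Measure",
    "PairCounts",
    "DoubleEntryTable",
    "SimilarityEstimate",
    "ZygosityComparison",
    "UndefinedEstimateError",
    "tabulate_pairs",
    "casewise_concordance",
    "double_entry",
    "phi_correlation",
    "pairwise_odds_ratio",
    "zygosity_difference_test",
    "round_half_up",
    "round_sig",
]

Z95 = 1.96


class UndefinedEstimateError(TwinpainError):
    """A similarity measure is undefined for the given counts."""


class Measure(str, Enum):
    CONCORDANCE = "casewise_concordance"
    CORRELATION = "correlation"
    ODDS_RATIO = "odds_ratio"


@dataclass(frozen=True)
class PairCounts:
    """Per-zygosity pair tally for one binary trait."""

    nc: int  # pairs with both twins affected
    nd: int  # pairs with exactly one affected
    n00: int  # pairs with neither affected
    zygosity: Zygosity = Zygosity.MZ
    trait: str = ""

    def __post_init__(self) -> None:
        for name in ("nc", "nd", "n00"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.nc + self.nd + self.n00


@dataclass(frozen=True)
class DoubleEntryTable:
    """Symmetric 2x2 table with each pair entered twice."""

    a: int  # both affected, double entered
    b: int  # discordant
    c: int  # discordant
    d: int  # both unaffected, double entered

    @property
    def n_pairs(self) -> int:
        return (self.a + self.b + self.c + self.d) // 2


@dataclass(frozen=True)
class SimilarityEstimate:
    """A similarity measure with its working-scale variance and 95% CI.

    ``variance`` lives on the measure's working scale: identity for the
    concordance, Fisher z for the correlation, log for the odds ratio.
    """

    measure: Measure
    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    zygosity: Zygosity | None = None
    trait: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence bounds must bracket the estimate")


@dataclass(frozen=True)
class ZygosityComparison:
    mz: SimilarityEstimate
    dz: SimilarityEstimate
    z_statistic: float
    p_one_sided: float
    p_two_sided: float


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up, the convention of the report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (half-up)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)


def _trait_value(record: IndividualRecord, trait: str) -> Tristate:
    value = getattr(record, trait)
    if not isinstance(value, Tristate):
        raise TwinpainError(f"{trait!r} is not a tristate trait")
    excluded = (trait == "lbp_life" and record.lbp_excluded) or (
        trait == "tlbp_current" and record.tlbp_excluded
    )
    return Tristate.MISSING if excluded else value


def tabulate_pairs(cohort: Cohort, trait: str, zygosity: Zygosity) -> PairCounts:
    """Count concordant/discordant/unaffected complete twin pairs.

    Pairs where either member is missing (or excluded) for the trait are
    dropped before counting, with the dropped count logged.
    """
    nc = nd = n00 = 0
    dropped = 0
    for t1, t2 in cohort.twin_pairs():
        if t1.zygosity is not zygosity:
            continue
        v1, v2 = _trait_value(t1, trait), _trait_value(t2, trait)
        if Tristate.MISSING in (v1, v2):
            dropped += 1
            continue
        k = (v1 is Tristate.CASE) + (v2 is Tristate.CASE)
        if k == 2:
            nc += 1
        elif k == 1:
            nd += 1
        else:
            n00 += 1
    if dropped:
        logger.info(
            "stage=tabulate_pairs trait=%s zygosity=%s dropped_missing=%d",
            trait, zygosity.value, dropped,
        )
    return PairCounts(nc=nc, nd=nd, n00=n00, zygosity=zygosity, trait=trait)


def casewise_concordance(counts: PairCounts) -> SimilarityEstimate:
    """P(co-twin affected | twin affected), estimated as 2Nc/(2Nc+Nd)."""
    nc, nd = counts.nc, counts.nd
    denom = 2 * nc + nd
    if denom == 0:
        raise UndefinedEstimateError(
            "casewise concordance undefined: no affected individuals"
        )
    est = 2 * nc / denom
    var = 4 * nc * nd * (nc + nd) / denom**4
    half = Z95 * math.sqrt(var)
    return SimilarityEstimate(
        measure=Measure.CONCORDANCE,
        estimate=est,
        variance=var,
        ci_low=max(0.0, est - half),
        ci_high=min(1.0, est + half),
        zygosity=counts.zygosity,
        trait=counts.trait,
    )


def double_entry(counts: PairCounts) -> DoubleEntryTable:
    """Enter each pair twice to form the symmetric 2x2 table."""
    return DoubleEntryTable(a=2 * counts.nc, b=counts.nd, c=counts.nd, d=2 * counts.n00)


def phi_correlation(
    table: DoubleEntryTable,
    zygosity: Zygosity | None = None,
    trait: str = "",
) -> SimilarityEstimate:
    """Phi (binary Pearson) correlation of the double-entry table.

    The interval is Fisher-z with n = number of pairs; the working-scale
    variance stored on the estimate is 1/(n-3) on the z scale.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise UndefinedEstimateError("phi undefined: zero margin in 2x2 table")
    phi = (a * d - b * c) / math.sqrt(math.prod(margins))
    n = table.n_pairs
    if n <= 3:
        raise UndefinedEstimateError("too few pairs for a Fisher-z interval")
    var_z = 1.0 / (n - 3)
    z = math.atanh(max(-0.999999, min(0.999999, phi)))
    half = Z95 * math.sqrt(var_z)
    return SimilarityEstimate(
        measure=Measure.CORRELATION,
        estimate=phi,
        variance=var_z,
        ci_low=math.tanh(z - half),
        ci_high=math.tanh(z + half),
        zygosity=zygosity,
        trait=trait,
    )


def pairwise_odds_ratio(
    table: DoubleEntryTable,
    zygosity: Zygosity | None = None,
    trait: str = "",
    continuity: str = "none",
) -> SimilarityEstimate:
    """Pairwise OR = ad/(bc) with a Woolf interval on the log scale.

    A zero cell makes the OR undefined by default; ``continuity="haldane"``
    adds 0.5 to every cell instead (off by default, since silent corrections
    distort small simulations).
    """
    cells = [float(table.a), float(table.b), float(table.c), float(table.d)]
    if any(v == 0 for v in cells):
        if continuity == "haldane":
            cells = [v + 0.5 for v in cells]
        else:
            raise UndefinedEstimateError(
                "odds ratio undefined: zero cell (enable Haldane-Anscombe "
                "continuity to proceed)"
            )
    a, b, c, d = cells
    est = (a * d) / (b * c)
    var_log = 1 / a + 1 / b + 1 / c + 1 / d
    half = Z95 * math.sqrt(var_log)
    log_est = math.log(est)
    return SimilarityEstimate(
        measure=Measure.ODDS_RATIO,
        estimate=est,
        variance=var_log,
        ci_low=math.exp(log_est - half),
        ci_high=math.exp(log_est + half),
        zygosity=zygosity,
        trait=trait,
    )


def _working_scale(est: SimilarityEstimate) -> float:
    if est.measure is Measure.CONCORDANCE:
        return est.estimate
    if est.measure is Measure.CORRELATION:
        return math.atanh(est.estimate)
    return math.log(est.estimate)


def zygosity_difference_test(
    mz: SimilarityEstimate, dz: SimilarityEstimate
) -> ZygosityComparison:
    """Normal z test of MZ - DZ on the measure's working scale.

    One-sided p is the upper-tail probability (alternative: MZ more similar);
    two-sided p doubles the smaller tail.
    """
    if mz.measure is not dz.measure:
        raise TwinpainError("cannot compare estimates of different measures")
    se = math.sqrt(mz.variance + dz.variance)
    if se == 0:
        raise UndefinedEstimateError("degenerate test: zero combined variance")
    z = (_working_scale(mz) - _working_scale(dz)) / se
    p1 = float(norm.sf(z))
    p2 = 2 * min(p1, 1 - p1)
    return ZygosityComparison(mz=mz, dz=dz, z_statistic=z, p_one_sided=p1, p_two_sided=p2)
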