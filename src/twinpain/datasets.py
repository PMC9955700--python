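"""Published reference tallies from a pediatric twin-family back-pain survey.

These small tables are the printed summary counts of the study whose analysis
this package re-implements; raw individual data were never deposited. The pair
tallies feed the similarity stage directly (they are sufficient statistics for
all three pair-similarity measures), and the case/control counts feed the
prevalence table. They double as back-validation fixtures: the similarity
stage must reproduce the study's printed estimates from them.
"""

from __future__ import annotations

import pandas as pd

from .datamodel import Zygosity
from .similarity import PairCounts

__all__ = [
    "PUBLISHED_PAIR_COUNTS",
    "PUBLISHED_PREVALENCE_COUNTS",
    "published_pair_counts",
    "pair_counts_frame",
    "prevalence_counts_frame",
]

#: (trait, zygosity) -> (Nc, Nd, N00): concordant / discordant / neither-affected pairs
PUBLISHED_PAIR_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("lbp_life", "MZ"): (19, 41, 215),
    ("lbp_life", "DZ"): (10, 59, 307),
    ("tlbp_current", "MZ"): (13, 36, 223),
    ("tlbp_current", "DZ"): (5, 52, 316),
}

#: (population, trait) -> (cases, controls)
PUBLISHED_PREVALENCE_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("twins", "lbp_life"): (158, 1144),
    ("twins", "tlbp_current"): (124, 1171),
    ("siblings", "lbp_life"): (51, 369),
    ("siblings", "tlbp_current"): (42, 378),
    ("mothers", "lbp_life"): (269, 371),
    ("mothers", "tlbp_current"): (170, 470),
    ("fathers", "lbp_life"): (226, 340),
    ("fathers", "tlbp_current"): (131, 435),
}


def published_pair_counts(trait: str, zygosity: Zygosity | str) -> PairCounts:
    z = Zygosity(zygosity)
    nc, nd, n00 = PUBLISHED_PAIR_COUNTS[(trait, z.value)]
    return PairCounts(nc=nc, nd=nd, n00=n00, zygosity=z, trait=trait)


def pair_counts_frame() -> pd.DataFrame:
    rows = [
        {"trait": trait, "zygosity": z, "nc": nc, "nd": nd, "n00": n00}
        for (trait, z), (nc, nd, n00) in PUBLISHED_PAIR_COUNTS.items()
    ]
    return pd.DataFrame(rows)


def prevalence_counts_frame() -> pd.DataFrame:
    rows = [
        {"population": pop, "trait": trait, "cases": a, "controls": b}
        for (pop, trait), (a, b) in PUBLISHED_PREVALENCE_COUNTS.items()
    ]
    return pd.DataFrame(rows)
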