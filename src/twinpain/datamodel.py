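"""Cohort data model, body-map regions, and questionnaire case definitions.

One row of a cohort file is one person in a twin family: a twin, the first
(oldest) sibling, or a parent. Binary pain/condition indicators are *tristate*
(case / control / missing): an unanswered item is never silently coerced to
control. Current pain is recorded as a set of body-map sites which are reduced
to nine anatomical regions; thoracolumbar back pain (TLBP) means pain in the
lower and/or middle back region.

Case definitions implemented here:

* ``lbp_life`` — lifetime low back pain of at least three months duration,
  excluding disease-related or severe-injury-related pain. Pain attributed to
  a *minor* injury does not exclude.
* ``tlbp_current`` — pain for most of the last month with at least one site in
  the lower/middle back, same serious-disease/injury exclusion.
* condition classifiers (migraine, non-migraine headache, growing pains,
  restless legs, iron-deficiency history, recurrent abdominal pain, other
  chronic pain) applied as rule tables over raw questionnaire items.
* two summed scales: anxious depression (0-36 adult, 0-26 child) and multiple
  sensory sensitivity (declared range 5-35 over seven 5-point items).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("twinpain")

__all__ = [
    "Tristate",
    "Role",
    "Zygosity",
    "IndividualRecord",
    "RegionProfile",
    "Cohort",
    "SITE_TO_REGION",
    "SITES",
    "REGIONS",
    "CONDITIONS",
    "SCALES",
    "SchemaError",
    "IntegrityError",
    "MappingError",
    "ScaleError",
    "ClassificationError",
    "read_cohort",
    "write_cohort",
    "write_site_map_sidecar",
    "map_sites_to_regions",
    "classify_back_pain",
    "classify_condition",
    "classify_cohort",
    "score_scale",
]


class TwinpainError(Exception):
    """Base class for package errors."""


class SchemaError(TwinpainError):
    """A cohort file is missing a mandatory column or is malformed."""


class IntegrityError(TwinpainError):
    """Duplicate or contradictory rows within a cohort file."""


class MappingError(TwinpainError):
    """An unknown body-map site code."""


class ScaleError(TwinpainError):
    """A scale item outside its declared range, or wrong item count."""


class ClassificationError(TwinpainError):
    """An unknown condition identifier."""


class Tristate(str, Enum):
    CASE = "case"
    CONTROL = "control"
    MISSING = "missing"


class Role(str, Enum):
    TWIN1 = "twin1"
    TWIN2 = "twin2"
    FIRST_SIBLING = "first_sibling"
    MOTHER = "mother"
    FATHER = "father"


class Zygosity(str, Enum):
    MZ = "MZ"
    DZ = "DZ"
    NOT_APPLICABLE = "not_applicable"


OFFSPRING_ROLES = (Role.TWIN1, Role.TWIN2, Role.FIRST_SIBLING)
TWIN_ROLES = (Role.TWIN1, Role.TWIN2)

# --------------------------------------------------------------------------
# Body map: 21 site codes partitioned into 9 regions. The lower-limb
# constituents (foot, ankle, shin, calf, thigh, hip) follow the published
# region definition; the remaining allocation (knees under lower limbs,
# shoulder-to-hand under upper limbs, face/forehead under head) is this
# package's fixed, versioned stand-in for the full body-map partition, which
# the source questionnaire does not enumerate site by site.
SITE_MAP_VERSION = "twinpain-sites-1"

REGIONS = (
    "lower_limbs",
    "upper_limbs",
    "chest",
    "abdomen",
    "head",
    "neck",
    "lower_back",
    "middle_back",
    "upper_back",
)

SITE_TO_REGION: dict[str, str] = {
    "head": "head",
    "face": "head",
    "forehead": "head",
    "neck": "neck",
    "chest": "chest",
    "abdomen": "abdomen",
    "upper_back": "upper_back",
    "middle_back": "middle_back",
    "lower_back": "lower_back",
    "shoulders": "upper_limbs",
    "elbows": "upper_limbs",
    "forearms": "upper_limbs",
    "wrists": "upper_limbs",
    "hands": "upper_limbs",
    "hips": "lower_limbs",
    "thighs": "lower_limbs",
    "knees": "lower_limbs",
    "shins": "lower_limbs",
    "calves": "lower_limbs",
    "ankles": "lower_limbs",
    "feet": "lower_limbs",
}
SITES = tuple(SITE_TO_REGION)
assert len(SITES) == 21

TLBP_REGIONS = ("lower_back", "middle_back")

CONDITIONS = (
    "migraine",
    "headache",
    "growing_pains",
    "recurrent_abdominal_pain",
    "chronic_pain_other",
    "restless_legs",
    "iron_deficiency_history",
)

#: scale name -> (n_items, item_min, item_max, total_min, total_max)
SCALES: dict[str, tuple[int, int, int, int, int]] = {
    "anxious_depression_adult": (18, 0, 2, 0, 36),
    "anxious_depression_child": (13, 0, 2, 0, 26),
    "sensory_sensitivity": (7, 1, 5, 5, 35),
}

# Default file dialect for tristate tokens; configurable per file.
DEFAULT_TRISTATE_DIALECT: dict[str, Tristate] = {
    "1": Tristate.CASE,
    "0": Tristate.CONTROL,
    "na": Tristate.MISSING,
    "": Tristate.MISSING,
    "case": Tristate.CASE,
    "control": Tristate.CONTROL,
    "missing": Tristate.MISSING,
}


@dataclass
class IndividualRecord:
    """One person of a twin family with traits, pain sites, and scores."""

    family_id: str
    role: Role
    zygosity: Zygosity = Zygosity.NOT_APPLICABLE
    age: float | None = None
    sex: str = "missing"  # {male, female, missing}
    pain_sites: frozenset[str] = frozenset()
    most_important_site: str | None = None
    lbp_life: Tristate = Tristate.MISSING
    tlbp_current: Tristate = Tristate.MISSING
    injury_flag: Tristate = Tristate.MISSING
    serious_injury_or_disease: Tristate = Tristate.MISSING
    migraine: Tristate = Tristate.MISSING
    headache: Tristate = Tristate.MISSING
    growing_pains: Tristate = Tristate.MISSING
    recurrent_abdominal_pain: Tristate = Tristate.MISSING
    chronic_pain_other: Tristate = Tristate.MISSING
    restless_legs: Tristate = Tristate.MISSING
    iron_deficiency_history: Tristate = Tristate.MISSING
    anxious_depression_score: int | None = None
    sensory_sensitivity_score: int | None = None
    # bookkeeping set by classify_cohort: excluded-from-analysis markers keep
    # denominators auditable instead of silently deleting rows.
    lbp_excluded: bool = False
    tlbp_excluded: bool = False

    def __post_init__(self) -> None:
        if self.role in TWIN_ROLES:
            if self.zygosity is Zygosity.NOT_APPLICABLE:
                raise IntegrityError(
                    f"twin {self.family_id}/{self.role.value} must declare zygosity"
                )
        elif self.zygosity is not Zygosity.NOT_APPLICABLE:
            raise IntegrityError(
                f"non-twin {self.family_id}/{self.role.value} cannot have zygosity"
            )
        if self.age is not None and self.age < 0:
            raise IntegrityError(f"negative age for {self.family_id}/{self.role.value}")

    @property
    def is_offspring(self) -> bool:
        return self.role in OFFSPRING_ROLES


@dataclass(frozen=True)
class RegionProfile:
    """Nine region indicators derived from body-map sites."""

    indicators: Mapping[str, bool]

    def __post_init__(self) -> None:
        if set(self.indicators) != set(REGIONS):
            raise MappingError("RegionProfile must carry exactly the 9 regions")

    def __getitem__(self, region: str) -> bool:
        return self.indicators[region]

    @property
    def tlbp_region(self) -> bool:
        return self.indicators["lower_back"] or self.indicators["middle_back"]

    def multiple_sites(self, exclude: Sequence[str] = ()) -> bool:
        """Pain in two or more regions outside ``exclude`` (the index regions)."""
        return sum(v for r, v in self.indicators.items() if r not in exclude) >= 2

    def positive_regions(self) -> frozenset[str]:
        return frozenset(r for r, v in self.indicators.items() if v)


def map_sites_to_regions(sites: Iterable[str]) -> RegionProfile:
    """Reduce marked body-map sites to the nine-region profile.

    Order-independent and idempotent; a region is positive iff at least one
    of its constituent sites is marked. Unknown codes raise ``MappingError``.
    """
    indicators = {r: False for r in REGIONS}
    for code in sites:
        region = SITE_TO_REGION.get(code)
        if region is None:
            raise MappingError(f"unknown body-map site code: {code!r}")
        indicators[region] = True
    return RegionProfile(indicators)


def write_site_map_sidecar(path: str | Path) -> None:
    """Write the JSON sidecar declaring the site->region mapping version."""
    payload = {"version": SITE_MAP_VERSION, "site_to_region": SITE_TO_REGION}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# Cohort container and delimited I/O

TRISTATE_COLUMNS = (
    "lbp_life",
    "tlbp_current",
    "injury_flag",
    "serious_injury_or_disease",
) + CONDITIONS

MANDATORY_COLUMNS = ("family_id", "role", "zygosity", "age", "sex",
                     "lbp_life", "tlbp_current")

CSV_COLUMNS = (
    "family_id",
    "role",
    "zygosity",
    "age",
    "sex",
    "pain_sites",
    "most_important_site",
    "lbp_life",
    "tlbp_current",
    "injury_flag",
    "serious_injury_or_disease",
    "migraine",
    "headache",
    "growing_pains",
    "recurrent_abdominal_pain",
    "chronic_pain_other",
    "restless_legs",
    "iron_deficiency_history",
    "anxious_depression_score",
    "sensory_sensitivity_score",
)


@dataclass
class Cohort:
    """A loaded cohort: records plus row-level validation warnings."""

    records: list[IndividualRecord]
    warnings: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[IndividualRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.family_id, None)
        return list(seen)

    def by_role(self, *roles: Role) -> list[IndividualRecord]:
        return [r for r in self.records if r.role in roles]

    def twin_pairs(self) -> list[tuple[IndividualRecord, IndividualRecord]]:
        """Complete (twin1, twin2) pairs; incomplete pairs are dropped with a log."""
        twins: dict[str, dict[Role, IndividualRecord]] = {}
        for r in self.records:
            if r.role in TWIN_ROLES:
                twins.setdefault(r.family_id, {})[r.role] = r
        pairs = []
        n_incomplete = 0
        for fid, members in twins.items():
            if Role.TWIN1 in members and Role.TWIN2 in members:
                pairs.append((members[Role.TWIN1], members[Role.TWIN2]))
            else:
                n_incomplete += 1
        if n_incomplete:
            logger.info("stage=pairing incomplete_twin_pairs_dropped=%d", n_incomplete)
        return pairs

    def relatives(self, role: Role) -> dict[str, IndividualRecord]:
        return {r.family_id: r for r in self.records if r.role is role}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "family_id": r.family_id,
                "role": r.role.value,
                "zygosity": r.zygosity.value,
                "age": r.age,
                "sex": r.sex,
                "pain_sites": ";".join(sorted(r.pain_sites)),
                "most_important_site": r.most_important_site or "",
                "anxious_depression_score": r.anxious_depression_score,
                "sensory_sensitivity_score": r.sensory_sensitivity_score,
                "lbp_excluded": r.lbp_excluded,
                "tlbp_excluded": r.tlbp_excluded,
            }
            for col in TRISTATE_COLUMNS:
                row[col] = getattr(r, col).value
            rows.append(row)
        return pd.DataFrame(rows)


def _parse_tristate(token: object, dialect: Mapping[str, Tristate]) -> Tristate:
    key = str(token).strip().lower()
    if key in ("nan", "none"):
        return Tristate.MISSING
    return dialect.get(key, Tristate.MISSING)


def read_cohort(
    path: str | Path,
    dialect: Mapping[str, Tristate] | None = None,
) -> Cohort:
    """Read a cohort CSV (one row per individual) into records.

    Unparseable tristate tokens become ``missing``. A missing mandatory column
    raises :class:`SchemaError` naming the column; a duplicated
    (family_id, role) raises :class:`IntegrityError`. Rows violating the
    most-important-site invariant load with a recorded warning.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    tri = dict(DEFAULT_TRISTATE_DIALECT)
    if dialect:
        tri.update({k.strip().lower(): v for k, v in dialect.items()})

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column missing: {col!r}")

    records: list[IndividualRecord] = []
    warnings: list[str] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        fid = row["family_id"].strip()
        role = Role(row["role"].strip())
        key = (fid, role.value)
        if key in seen:
            raise IntegrityError(f"duplicate individual: family {fid!r} role {role.value}")
        seen.add(key)
        zyg_token = row.get("zygosity", "").strip()
        zygosity = (
            Zygosity(zyg_token)
            if zyg_token in ("MZ", "DZ")
            else Zygosity.NOT_APPLICABLE
        )
        sites_token = row.get("pain_sites", "")
        sites = frozenset(s for s in str(sites_token).split(";") if s)
        unknown = sites - set(SITES)
        if unknown:
            raise MappingError(f"row {i}: unknown site codes {sorted(unknown)}")
        mis = row.get("most_important_site", "").strip() or None
        if mis is not None and mis not in sites:
            warnings.append(
                f"row {i} ({fid}/{role.value}): most_important_site {mis!r} "
                "not among marked pain_sites"
            )
        age_token = str(row.get("age", "")).strip()
        sex_token = str(row.get("sex", "")).strip().lower()

        def _score(col: str) -> int | None:
            tok = str(row.get(col, "")).strip()
            try:
                return int(float(tok))
            except ValueError:
                return None

        kwargs = {
            col: _parse_tristate(row.get(col, ""), tri) for col in TRISTATE_COLUMNS
            if col in df.columns
        }
        records.append(
            IndividualRecord(
                family_id=fid,
                role=role,
                zygosity=zygosity,
                age=float(age_token) if age_token else None,
                sex=sex_token if sex_token in ("male", "female") else "missing",
                pain_sites=sites,
                most_important_site=mis,
                anxious_depression_score=_score("anxious_depression_score"),
                sensory_sensitivity_score=_score("sensory_sensitivity_score"),
                **kwargs,
            )
        )
    cohort = Cohort(records=records, warnings=warnings)
    logger.info(
        "stage=read_cohort path=%s rows=%d families=%d warnings=%d",
        path, len(records), len(cohort.family_ids), len(warnings),
    )
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write records back to the canonical CSV schema (1/0/NA tristates)."""
    token = {Tristate.CASE: "1", Tristate.CONTROL: "0", Tristate.MISSING: "NA"}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in cohort.records:
            row = []
            for col in CSV_COLUMNS:
                if col in TRISTATE_COLUMNS:
                    row.append(token[getattr(r, col)])
                elif col == "pain_sites":
                    row.append(";".join(sorted(r.pain_sites)))
                elif col == "most_important_site":
                    row.append(r.most_important_site or "")
                elif col == "zygosity":
                    row.append(r.zygosity.value if r.zygosity is not Zygosity.NOT_APPLICABLE else "")
                elif col == "role":
                    row.append(r.role.value)
                elif col == "age":
                    row.append("" if r.age is None else f"{r.age:g}")
                elif col in ("anxious_depression_score", "sensory_sensitivity_score"):
                    v = getattr(r, col)
                    row.append("" if v is None else str(v))
                else:
                    row.append(getattr(r, col))
            writer.writerow(row)


# --------------------------------------------------------------------------
# Case definitions


@dataclass(frozen=True)
class BackPainStatus:
    lbp_life: Tristate
    tlbp_current: Tristate
    lbp_excluded: bool = False
    tlbp_excluded: bool = False


def classify_back_pain(record: IndividualRecord) -> BackPainStatus:
    """Apply the two back-pain case definitions to one record.

    The raw ``lbp_life`` field is the lifetime >=3-month low-back-pain
    endorsement; the raw ``tlbp_current`` field is the "pain for most of the
    last month" endorsement, localized via ``pain_sites``. Disease-related or
    severe-injury-related pain is excluded from analysis (flagged, the value
    reverts to control); minor-injury attribution never excludes. Missing
    inputs propagate as missing.
    """
    serious = record.serious_injury_or_disease is Tristate.CASE

    lbp = record.lbp_life
    lbp_excluded = False
    if lbp is Tristate.CASE and serious:
        lbp, lbp_excluded = Tristate.CONTROL, True

    tlbp = record.tlbp_current
    tlbp_excluded = False
    if tlbp is Tristate.CASE:
        if map_sites_to_regions(record.pain_sites).tlbp_region:
            if serious:
                tlbp, tlbp_excluded = Tristate.CONTROL, True
        else:
            tlbp = Tristate.CONTROL
    return BackPainStatus(lbp, tlbp, lbp_excluded, tlbp_excluded)


def classify_cohort(cohort: Cohort) -> Cohort:
    """Return a cohort whose back-pain fields hold resolved case status."""
    out = []
    n_lbp_excl = n_tlbp_excl = 0
    for r in cohort.records:
        st = classify_back_pain(r)
        n_lbp_excl += st.lbp_excluded
        n_tlbp_excl += st.tlbp_excluded
        out.append(
            replace(
                r,
                lbp_life=st.lbp_life,
                tlbp_current=st.tlbp_current,
                lbp_excluded=st.lbp_excluded,
                tlbp_excluded=st.tlbp_excluded,
            )
        )
    logger.info(
        "stage=classify records=%d lbp_excluded=%d tlbp_excluded=%d",
        len(out), n_lbp_excl, n_tlbp_excl,
    )
    return Cohort(records=out, warnings=list(cohort.warnings))


_MIGRAINE_FEATURES = (
    "unilateral",
    "pulsating",
    "moderate_or_severe",
    "aggravated_by_activity",
)
_MIGRAINE_REQUIRED = (
    "attacks_at_least_5",
    "duration_4_to_72h",
    "nausea_or_vomiting",
    "photophobia_and_phonophobia",
) + _MIGRAINE_FEATURES
_GROWING_PAINS_REQUIRED = (
    "bilateral_lower_limb_pain",
    "onset_age",
    "night_pain",
    "no_significant_limitation",
    "orthopedic_disorder",
    "abnormal_tests",
)
_RLS_REQUIRED = ("urge_to_move_at_rest", "worse_at_rest", "relieved_by_movement",
                 "worse_evening_or_night")


def _items_complete(items: Mapping[str, object], keys: Sequence[str]) -> bool:
    return all(items.get(k) is not None for k in keys)


def classify_condition(
    record: IndividualRecord | None,
    condition: str,
    raw_items: Mapping[str, object],
) -> Tristate:
    """Apply one condition's diagnostic rule table to raw questionnaire items.

    Returns ``missing`` (never control) whenever a required item is absent.
    Headache is only positive when the migraine criteria are *not* met.
    """
    if condition == "migraine":
        if not _items_complete(raw_items, _MIGRAINE_REQUIRED):
            return Tristate.MISSING
        n_features = sum(bool(raw_items[k]) for k in _MIGRAINE_FEATURES)
        accompanied = bool(raw_items["nausea_or_vomiting"]) or bool(
            raw_items["photophobia_and_phonophobia"]
        )
        ok = (
            bool(raw_items["attacks_at_least_5"])
            and bool(raw_items["duration_4_to_72h"])
            and n_features >= 2
            and accompanied
        )
        return Tristate.CASE if ok else Tristate.CONTROL

    if condition == "headache":
        migraine = classify_condition(record, "migraine", raw_items)
        if migraine is Tristate.MISSING:
            return Tristate.MISSING
        if migraine is Tristate.CASE:
            return Tristate.CONTROL
        if not _items_complete(raw_items, ("recurring_headaches", "duration_4_to_72h")):
            return Tristate.MISSING
        ok = bool(raw_items["recurring_headaches"]) and bool(raw_items["duration_4_to_72h"])
        return Tristate.CASE if ok else Tristate.CONTROL

    if condition == "growing_pains":
        if not _items_complete(raw_items, _GROWING_PAINS_REQUIRED):
            return Tristate.MISSING
        onset = float(raw_items["onset_age"])  # type: ignore[arg-type]
        ok = (
            bool(raw_items["bilateral_lower_limb_pain"])
            and 3 <= onset <= 12
            and bool(raw_items["night_pain"])
            and bool(raw_items["no_significant_limitation"])
            and not bool(raw_items["orthopedic_disorder"])
            and not bool(raw_items["abnormal_tests"])
        )
        return Tristate.CASE if ok else Tristate.CONTROL

    if condition == "restless_legs":
        if not _items_complete(raw_items, _RLS_REQUIRED):
            return Tristate.MISSING
        return (
            Tristate.CASE
            if all(bool(raw_items[k]) for k in _RLS_REQUIRED)
            else Tristate.CONTROL
        )

    if condition == "iron_deficiency_history":
        # two-part question, both parts required
        if not _items_complete(raw_items, ("ever_iron_deficiency", "doctor_diagnosed")):
            return Tristate.MISSING
        ok = bool(raw_items["ever_iron_deficiency"]) and bool(raw_items["doctor_diagnosed"])
        return Tristate.CASE if ok else Tristate.CONTROL

    if condition == "recurrent_abdominal_pain":
        if raw_items.get("recurrent_abdominal_pain") is None:
            return Tristate.MISSING
        return (
            Tristate.CASE
            if bool(raw_items["recurrent_abdominal_pain"])
            else Tristate.CONTROL
        )

    if condition == "chronic_pain_other":
        if raw_items.get("chronic_pain_other") is None:
            return Tristate.MISSING
        return (
            Tristate.CASE if bool(raw_items["chronic_pain_other"]) else Tristate.CONTROL
        )

    raise ClassificationError(f"unknown condition id: {condition!r}")


def score_scale(items: Sequence[int], scale: str) -> int:
    """Sum a questionnaire scale after validating every item's range."""
    if scale not in SCALES:
        raise ScaleError(f"unknown scale: {scale!r}")
    n_items, lo, hi, total_lo, total_hi = SCALES[scale]
    if len(items) != n_items:
        raise ScaleError(f"{scale} expects {n_items} items, got {len(items)}")
    for v in items:
        if not (lo <= v <= hi):
            raise ScaleError(f"{scale} item value {v} outside [{lo}, {hi}]")
    total = int(sum(items))
    if not (total_lo <= total <= total_hi):
        raise ScaleError(f"{scale} total {total} outside declared range "
                         f"[{total_lo}, {total_hi}]")
    return total
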