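"""End-to-end orchestration: simulate or ingest, classify, and report.

``run_pipeline`` turns a structured config (dict or YAML file) into a bundle
of tidy report tables — prevalence, pair counts, pair similarity with MZ/DZ
difference tests, per-relative family associations, and univariate +
multivariable association tables — together with a run manifest (config
snapshot, seeds, input checksums, per-stage record counts) so each table is
traceable and reruns with identical inputs reproduce identical outputs.

Report tables follow a fixed rounding convention (half-up, two decimals for
proportions and correlations, three significant figures for odds ratios);
internal values keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .association import build_association_table, expected_cross_trait_check
from .datamodel import (
    Cohort,
    Role,
    SchemaError,
    Tristate,
    TwinpainError,
    classify_cohort,
    read_cohort,
)
from .family import family_table
from .similarity import (
    Measure,
    PairCounts,
    UndefinedEstimateError,
    casewise_concordance,
    double_entry,
    pairwise_odds_ratio,
    phi_correlation,
    round_half_up,
    round_sig,
    tabulate_pairs,
    zygosity_difference_test,
)
from .datamodel import Zygosity
from .simulate import ACEConfig, default_study_config, simulate_cohort

logger = logging.getLogger("twinpain")

__all__ = [
    "RunManifest",
    "ReportBundle",
    "run_pipeline",
    "prevalence_table",
    "prevalence_table_from_counts",
    "similarity_table",
    "pair_counts_table",
    "read_counts_file",
]

POPULATION_ROLES = {
    "twins": (Role.TWIN1, Role.TWIN2),
    "siblings": (Role.FIRST_SIBLING,),
    "mothers": (Role.MOTHER,),
    "fathers": (Role.FATHER,),
}

BACK_PAIN_TRAITS = ("lbp_life", "tlbp_current")


@dataclass
class RunManifest:
    """Traceability record: every reported table maps back to these inputs."""

    config: dict[str, Any]
    seed: int | None
    software_version: str = __version__
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "software_version": self.software_version,
                "input_checksums": self.input_checksums,
                "stage_counts": self.stage_counts,
                "notes": self.notes,
            },
            indent=1,
            sort_keys=True,
            default=str,
        )


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    manifest: RunManifest
    flagged: list[str] = field(default_factory=list)  # non-converged fits

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "manifest.json").write_text(self.manifest.to_json())
        (outdir / "report.txt").write_text(self.render_text())
        logger.info("stage=write outdir=%s tables=%d", outdir, len(self.tables))

    def render_text(self) -> str:
        chunks = []
        for name, table in self.tables.items():
            chunks.append(f"== {name} ==\n{table.to_string(index=False)}\n")
        return "\n".join(chunks)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# Individual report tables


def prevalence_table(cohort: Cohort) -> pd.DataFrame:
    """Case/control counts and percentages per population and back-pain trait.

    Percentages are computed over non-missing classified individuals
    (excluded-from-analysis records count as neither case nor control), so
    every N is derived from the case + control sum.
    """
    rows = []
    for pop, roles in POPULATION_ROLES.items():
        members = cohort.by_role(*roles)
        for trait in BACK_PAIN_TRAITS:
            excl_attr = "lbp_excluded" if trait == "lbp_life" else "tlbp_excluded"
            cases = controls = 0
            for r in members:
                if getattr(r, excl_attr):
                    continue
                v = getattr(r, trait)
                if v is Tristate.CASE:
                    cases += 1
                elif v is Tristate.CONTROL:
                    controls += 1
            rows.append(_prevalence_row(pop, trait, cases, controls))
    return pd.DataFrame(rows)


def _prevalence_row(pop: str, trait: str, cases: int, controls: int) -> dict:
    n = cases + controls
    pct = round_half_up(100 * cases / n, 1) if n else float("nan")
    return {
        "population": pop,
        "trait": trait,
        "cases": cases,
        "controls": controls,
        "n": n,
        "pct_cases": pct,
        "pct_controls": round_half_up(100 * controls / n, 1) if n else float("nan"),
    }


def prevalence_table_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Prevalence table from a (population, trait, cases, controls) frame."""
    return pd.DataFrame(
        [
            _prevalence_row(r.population, r.trait, int(r.cases), int(r.controls))
            for r in counts.itertuples()
        ]
    )


def pair_counts_table(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for trait in BACK_PAIN_TRAITS:
        for z in (Zygosity.MZ, Zygosity.DZ):
            c = tabulate_pairs(cohort, trait, z)
            rows.append(
                {"trait": trait, "zygosity": z.value, "nc": c.nc, "nd": c.nd,
                 "n00": c.n00}
            )
    return pd.DataFrame(rows)


def similarity_table(
    counts_by_zygosity: dict[Zygosity, PairCounts],
    measures: tuple[str, ...] = ("concordance", "correlation", "or"),
    continuity: str = "none",
) -> pd.DataFrame:
    """Tidy similarity table (per measure and zygosity, with MZ-DZ tests).

    Point estimates are reported rounded per the table convention (two
    decimals for concordance/correlation, three significant figures for ORs
    and their CI bounds); p-values to three decimals.
    """
    mz, dz = counts_by_zygosity[Zygosity.MZ], counts_by_zygosity[Zygosity.DZ]
    fitters = {
        "concordance": lambda c: casewise_concordance(c),
        "correlation": lambda c: phi_correlation(double_entry(c), c.zygosity, c.trait),
        "or": lambda c: pairwise_odds_ratio(double_entry(c), c.zygosity, c.trait,
                                            continuity=continuity),
    }
    rows = []
    for key in measures:
        try:
            est_mz, est_dz = fitters[key](mz), fitters[key](dz)
        except UndefinedEstimateError as exc:
            rows.append({"trait": mz.trait, "measure": key, "error": str(exc)})
            continue
        comp = zygosity_difference_test(est_mz, est_dz)
        for z, est in ((Zygosity.MZ, est_mz), (Zygosity.DZ, est_dz)):
            if key == "or":
                fmt = lambda v: round_sig(v, 3)
            else:
                fmt = lambda v: round_half_up(v, 2)
            rows.append(
                {
                    "trait": est.trait,
                    "measure": key,
                    "zygosity": z.value,
                    "estimate": fmt(est.estimate),
                    "ci_low": fmt(est.ci_low),
                    "ci_high": fmt(est.ci_high),
                    "estimate_raw": est.estimate,
                    "p_one_sided": round_half_up(comp.p_one_sided, 3),
                    "p_two_sided": round_half_up(comp.p_two_sided, 3),
                }
            )
    return pd.DataFrame(rows)


def read_counts_file(path: str | Path) -> dict[str, dict[Zygosity, PairCounts]]:
    """Read a literal pair-counts CSV (trait, zygosity, nc, nd, n00 per row)."""
    df = pd.read_csv(path)
    required = {"trait", "zygosity", "nc", "nd", "n00"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"counts file missing columns: {sorted(missing)}")
    out: dict[str, dict[Zygosity, PairCounts]] = {}
    for r in df.itertuples():
        z = Zygosity(r.zygosity)
        out.setdefault(r.trait, {})[z] = PairCounts(
            nc=int(r.nc), nd=int(r.nd), n00=int(r.n00), zygosity=z, trait=r.trait
        )
    return out


# --------------------------------------------------------------------------
# Orchestration


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise SchemaError("config file must hold a mapping")
        return loaded
    return dict(config)


def run_pipeline(config: dict | str | Path, seed: int | None = None) -> ReportBundle:
    """Run the full analysis described by ``config``.

    Config keys (exactly one input source):

    * ``counts``: path to a literal pair-counts CSV — similarity stage only;
    * ``cohort_csv``: path to a cohort file;
    * ``simulate``: mapping of :class:`~twinpain.simulate.ACEConfig` overrides
      (or ``{}`` for the default study conditions).

    Optional: ``seed`` (overridden by the ``seed`` argument), ``continuity``,
    ``association: false`` to skip the regression tables. Fits that fail to
    converge are recorded in ``bundle.flagged``.
    """
    cfg = _load_config(config)
    sources = [k for k in ("counts", "cohort_csv", "simulate") if k in cfg]
    if len(sources) != 1:
        raise SchemaError(
            f"config must name exactly one of counts/cohort_csv/simulate, got {sources}"
        )
    seed = seed if seed is not None else cfg.get("seed", 0)
    manifest = RunManifest(config=cfg, seed=seed)
    tables: dict[str, pd.DataFrame] = {}
    flagged: list[str] = []
    continuity = cfg.get("continuity", "none")

    if "counts" in cfg:
        path = Path(cfg["counts"])
        if not path.exists():
            raise SchemaError(f"counts file not found: {path}")
        manifest.input_checksums[str(path)] = _sha256(path)
        by_trait = read_counts_file(path)
        sim_rows = []
        for trait, by_z in by_trait.items():
            if {Zygosity.MZ, Zygosity.DZ} <= set(by_z):
                sim_rows.append(similarity_table(by_z, continuity=continuity))
        tables["similarity"] = pd.concat(sim_rows, ignore_index=True)
        manifest.stage_counts["counts"] = {
            "traits": len(by_trait),
            "pairs": int(sum(c.total for by_z in by_trait.values()
                             for c in by_z.values())),
        }
        return ReportBundle(tables=tables, manifest=manifest, flagged=flagged)

    if "cohort_csv" in cfg:
        path = Path(cfg["cohort_csv"])
        cohort = read_cohort(path, dialect=cfg.get("dialect"))
        manifest.input_checksums[str(path)] = _sha256(path)
    else:
        sim_cfg = cfg.get("simulate") or {}
        if sim_cfg.get("default_study", True):
            overrides = {k: v for k, v in sim_cfg.items() if k != "default_study"}
            ace = default_study_config(seed=seed, **overrides)
        else:
            overrides = {k: v for k, v in sim_cfg.items() if k != "default_study"}
            ace = ACEConfig(seed=seed, **overrides)
        cohort = simulate_cohort(ace)

    if not cohort.records:
        raise SchemaError("empty cohort: nothing to analyse")

    loaded = len(cohort.records)
    cohort = classify_cohort(cohort)
    excluded = sum(r.lbp_excluded for r in cohort.records)
    manifest.stage_counts["classify"] = {
        "loaded": loaded,
        "lbp_excluded": excluded,
        "analysed": loaded - excluded,
    }

    tables["prevalence"] = prevalence_table(cohort)
    tables["pair_counts"] = pair_counts_table(cohort)

    sim_rows = []
    for trait in BACK_PAIN_TRAITS:
        by_z = {
            z: tabulate_pairs(cohort, trait, z) for z in (Zygosity.MZ, Zygosity.DZ)
        }
        sim_rows.append(similarity_table(by_z, continuity=continuity))
    tables["similarity"] = pd.concat(sim_rows, ignore_index=True)

    fam_rows = [family_table(cohort, trait, seed=seed) for trait in BACK_PAIN_TRAITS]
    fam = pd.concat(fam_rows, ignore_index=True)
    tables["family"] = fam
    flagged.extend(
        f"family:{r.trait}:{r.relative}" for r in fam.itertuples()
        if not r.converged
    )

    if cfg.get("association", True):
        for outcome in BACK_PAIN_TRAITS:
            for predictor_set in ("regions", "conditions"):
                for population in ("twins_and_siblings", "mothers", "fathers"):
                    name = f"assoc_{outcome}_{predictor_set}_{population}"
                    try:
                        table = build_association_table(
                            cohort, outcome, predictor_set, population
                        )
                    except TwinpainError as exc:
                        manifest.notes.append(f"{name}: {exc}")
                        continue
                    df = table.to_dataframe()
                    tables[name] = df
                    flagged.extend(
                        f"{name}:{row.predictor}" for row in df.itertuples()
                        if not pd.notna(row.or_multi)
                    )
        control = expected_cross_trait_check(cohort)
        tables["cross_trait_check"] = pd.DataFrame(
            [
                {
                    "population": pop,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "n": res.n,
                    "model": res.model,
                }
                for pop, res in control.items()
            ]
        )

    manifest.stage_counts["tables"] = {"emitted": len(tables)}
    return ReportBundle(tables=tables, manifest=manifest, flagged=flagged)
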