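"""Study orchestration: subgroup analyses, sensitivity analyses, reporting.

Runs the full analysis sequence — build risk intervals, compute
ascertainment weights within each analysis subgroup, fit weighted Cox
models, and emit one report row per term (hazard ratio, robust 95%
confidence interval, p, subjects, person-years, events) — for a cohort read
from disk or simulated in-process.  Weights are recomputed inside every
subgroup because sampling fractions depend on the sample they calibrate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import BuildResult, build_cohort
from .cox import ConvergenceError, ModelSpec, fit, schoenfeld_test, wald_interaction
from .fp import best_fp_vs_linear
from .simulate import GENES, SimConfig, ascertain, read_cohort, simulate_families
from .weights import (IncidenceTable, assign_weights, compute_weights,
                      default_carrier_incidence, default_population_incidence)

__all__ = ["RunConfig", "StudyResult", "run_study", "summarize_cohort",
           "ALL_ANALYSES"]

ALL_ANALYSES = ("carriers_continuous", "carriers_who", "noncarriers_continuous",
                "noncarriers_who", "per_gene", "heterodimers", "per_site",
                "sex_specific", "interactions")

HETERODIMERS = {"MutLalpha": ("MLH1", "PMS2"), "MutSalpha": ("MSH2", "MSH6")}
SITE_GROUPS = {"right": ("right",), "left_rectosigmoid": ("left", "rectosigmoid"),
               "rectum": ("rectum",)}
ADJUSTMENT = ("sex", "country", "smoke20", "alcohol20")


@dataclass
class RunConfig:
    """One study run: inputs, requested analyses, options."""
    cohort_path: str | None = None
    carrier_incidence_path: str | None = None
    population_incidence_path: str | None = None
    analyses: tuple = ALL_ANALYSES
    verified_only: bool = False
    neoplasia_outcome: bool = False
    merge_degenerate_strata: bool = False
    weight_stratify_by: str = "interview"
    weight_competing_adjust: bool = True
    weight_min_stratum_count: int = 0
    ties: str = "breslow"
    cluster_correction: bool = False
    simulation: SimConfig | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        if self.cohort_path is None and self.simulation is None:
            raise ValueError("need either cohort_path or a simulation block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("carrier_incidence", "noncarrier_incidence"):
                if key in sim:
                    t = sim[key]
                    sim[key] = IncidenceTable(
                        np.asarray(t["age_lo"], float),
                        np.asarray(t["age_hi"], float),
                        np.asarray(t["rate"], float), label=t.get("label", ""))
            if "recruitment_age_range" in sim:
                sim["recruitment_age_range"] = tuple(sim["recruitment_age_range"])
            sim = SimConfig(**sim)
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(simulation=sim, **raw)


@dataclass
class StudyResult:
    rows: pd.DataFrame
    build: BuildResult
    summaries: dict
    weight_tables: dict
    manifest: dict
    records: pd.DataFrame = field(repr=False, default=None)


def _usable_covariates(records: pd.DataFrame, wanted) -> tuple:
    """Drop adjustment covariates that are constant in this subgroup."""
    keep = []
    for cov in wanted:
        if cov in records.columns and records[cov].nunique() > 1:
            keep.append(cov)
    return tuple(keep)


def _term_label(term: str) -> str:
    return {"bmi5": "BMI (per 5 kg m-2)", "who_underweight": "underweight",
            "who_overweight": "overweight", "who_obese": "obese"}.get(term, term)


def _fit_rows(records, incidence, *, analysis, group, exposure, covariates,
              ties, cluster_correction, merge_degenerate, stratify_by,
              competing_adjust, min_stratum_count,
              diagnostics=False) -> tuple[list, object]:
    """Weight the subgroup, fit, and translate the fit into report rows."""
    base = {"analysis": analysis, "group": group, "n": len(records),
            "person_years": float(records["exit_age"].sum()),
            "events": int(records["event"].sum())}
    if base["events"] < 2:
        return [{**base, "term": _term_label(exposure), "hr": np.nan,
                 "hr_ci_low": np.nan, "hr_ci_high": np.nan,
                 "robust_se": np.nan, "p": np.nan,
                 "note": "not estimable (<2 events)"}], None
    wt = compute_weights(records, incidence, stratify_by=stratify_by,
                         competing_adjust=competing_adjust,
                         min_stratum_count=min_stratum_count,
                         merge_degenerate=merge_degenerate)
    weighted = assign_weights(records, wt, incidence)
    spec = ModelSpec(exposure=exposure,
                     covariates=_usable_covariates(records, covariates),
                     ties=ties, cluster_correction=cluster_correction)
    try:
        f = fit(weighted, spec, weight_col="weight")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as e:
        return [{**base, "term": _term_label(exposure), "hr": np.nan,
                 "hr_ci_low": np.nan, "hr_ci_high": np.nan,
                 "robust_se": np.nan, "p": np.nan,
                 "note": f"not estimable ({e})"}], wt
    rows = []
    summ = f.summary()
    exposure_cols = f.groups[exposure]
    for col in exposure_cols:
        r = summ.loc[col]
        rows.append({**base, "term": _term_label(col), "hr": r["hr"],
                     "hr_ci_low": r["hr_ci_low"], "hr_ci_high": r["hr_ci_high"],
                     "robust_se": r["robust_se"], "p": r["p"], "note": ""})
    if diagnostics:
        empty = {"hr": np.nan, "hr_ci_low": np.nan, "hr_ci_high": np.nan,
                 "robust_se": np.nan}
        try:
            ph = schoenfeld_test(f)
            rows.append({**base, **empty, "term": "PH test (scaled Schoenfeld)",
                         "p": float(ph.loc[exposure_cols[0], "p"]),
                         "note": f"chi2={ph.loc[exposure_cols[0], 'chi2']:.3f}"})
        except ValueError as e:
            rows.append({**base, **empty, "term": "PH test (scaled Schoenfeld)",
                         "p": np.nan, "note": f"not computed ({e})"})
        if exposure == "bmi5":
            try:
                cmp_ = best_fp_vs_linear(weighted, spec, weight_col="weight")
                rows.append({**base, **empty,
                             "term": "fractional polynomial vs linear",
                             "p": cmp_.p,
                             "note": f"best powers {cmp_.best_powers}"})
            except (ConvergenceError, ValueError) as e:
                rows.append({**base, **empty,
                             "term": "fractional polynomial vs linear",
                             "p": np.nan, "note": f"not computed ({e})"})
    return rows, (wt, f)


def summarize_cohort(records: pd.DataFrame) -> dict:
    """Descriptive tables: counts and means by carrier and affection status,
    plus verification-source and tumour-site tallies for cases.

    Accepts either subject tables or built records; statistics are computed
    for whichever columns are present.  Empty input yields empty tables.
    """
    out = {}
    if len(records) == 0:
        out["baseline"] = pd.DataFrame()
        out["verification"] = pd.DataFrame()
        return out
    df = records.copy()
    if "event" in df.columns:
        df["affected"] = df["event"].astype(bool)
    else:
        df["affected"] = df["crc_age"].notna()
    rows = []
    for (carrier, affected), grp in df.groupby(["carrier", "affected"]):
        row = {"carrier": carrier,
               "affected": "affected" if affected else "unaffected",
               "n": len(grp),
               "n_female": int((grp["sex"] == "female").sum()),
               "n_smoke_ever": int((grp["smoke20"] == "ever").sum()),
               "n_alcohol_ever": int((grp["alcohol20"] == "ever").sum())}
        for gene in GENES:
            row[f"n_{gene}"] = int((grp["gene"] == gene).sum())
        for country, cnt in grp["country"].value_counts().items():
            row[f"n_country_{country}"] = int(cnt)
        for col, name in (("height_m", "height_m"), ("weight20_kg", "weight20_kg"),
                          ("bmi20", "bmi20")):
            if col in grp.columns:
                row[f"mean_{name}"] = float(grp[col].mean())
                row[f"sd_{name}"] = float(grp[col].std())
        rows.append(row)
    out["baseline"] = pd.DataFrame(rows)
    cases = df[df["affected"]]
    tallies = []
    for carrier, grp in cases.groupby("carrier"):
        row = {"carrier": carrier}
        for src, cnt in grp["crc_verified"].value_counts().items():
            if src:
                row[f"verified_{src}"] = int(cnt)
        for site, cnt in grp["tumour_site"].value_counts().items():
            if site:
                row[f"site_{site}"] = int(cnt)
        tallies.append(row)
    out["verification"] = pd.DataFrame(tallies)
    return out


def run_study(config: RunConfig) -> StudyResult:
    """Execute every requested analysis and collect the report rows.

    Each subgroup gets its own sampling weights (its own stratum counts
    against the relevant external incidence table: carrier rates for
    carriers, general-population rates for non-carriers).  Subgroups with
    fewer than two events yield a not-estimable row and the run continues.
    Site-specific analyses censor cancers at other sites at their diagnosis
    age.  A reproducibility manifest (config hash, seed, package versions)
    accompanies every run.
    """
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        subjects = ascertain(simulate_families(sim), sim)
    else:
        subjects = read_cohort(config.cohort_path)

    carrier_inc = (IncidenceTable.from_csv(config.carrier_incidence_path, "carrier")
                   if config.carrier_incidence_path else default_carrier_incidence())
    pop_inc = (IncidenceTable.from_csv(config.population_incidence_path, "population")
               if config.population_incidence_path else default_population_incidence())

    outcome = "neoplasia" if config.neoplasia_outcome else "crc"
    build = build_cohort(subjects, outcome_mode=outcome,
                         verified_only=config.verified_only)
    records = build.records
    carriers = records[records["carrier"] == "carrier"].reset_index(drop=True)
    noncarr = records[records["carrier"] == "noncarrier"].reset_index(drop=True)

    opts = dict(ties=config.ties, cluster_correction=config.cluster_correction,
                merge_degenerate=config.merge_degenerate_strata,
                stratify_by=config.weight_stratify_by,
                competing_adjust=config.weight_competing_adjust,
                min_stratum_count=config.weight_min_stratum_count)
    rows, weight_tables = [], {}

    def record(result, key):
        new_rows, extra = result
        rows.extend(new_rows)
        if extra is not None:
            weight_tables[key] = extra[0] if isinstance(extra, tuple) else extra

    for analysis in config.analyses:
        if analysis == "carriers_continuous":
            record(_fit_rows(carriers, carrier_inc, analysis=analysis,
                             group="carriers", exposure="bmi5",
                             covariates=ADJUSTMENT + ("gene",),
                             diagnostics=True, **opts), analysis)
        elif analysis == "carriers_who":
            record(_fit_rows(carriers, carrier_inc, analysis=analysis,
                             group="carriers", exposure="who_category",
                             covariates=ADJUSTMENT + ("gene",), **opts), analysis)
        elif analysis == "noncarriers_continuous":
            record(_fit_rows(noncarr, pop_inc, analysis=analysis,
                             group="noncarriers", exposure="bmi5",
                             covariates=ADJUSTMENT, diagnostics=True, **opts),
                   analysis)
        elif analysis == "noncarriers_who":
            record(_fit_rows(noncarr, pop_inc, analysis=analysis,
                             group="noncarriers", exposure="who_category",
                             covariates=ADJUSTMENT, **opts), analysis)
        elif analysis == "per_gene":
            for gene in GENES:
                sub = carriers[carriers["gene"] == gene].reset_index(drop=True)
                record(_fit_rows(sub, carrier_inc, analysis=analysis,
                                 group=gene, exposure="bmi5",
                                 covariates=ADJUSTMENT, **opts),
                       f"{analysis}_{gene}")
        elif analysis == "heterodimers":
            for name, genes in HETERODIMERS.items():
                sub = carriers[carriers["gene"].isin(genes)].reset_index(drop=True)
                record(_fit_rows(sub, carrier_inc, analysis=analysis,
                                 group=name, exposure="bmi5",
                                 covariates=ADJUSTMENT + ("gene",), **opts),
                       f"{analysis}_{name}")
        elif analysis == "per_site":
            for name, sites in SITE_GROUPS.items():
                sub = carriers.copy()
                other_site = (sub["event"] == 1) & ~sub["tumour_site"].isin(sites)
                sub.loc[other_site, "event"] = 0   # censored at diagnosis age
                record(_fit_rows(sub.reset_index(drop=True), carrier_inc,
                                 analysis=analysis, group=name, exposure="bmi5",
                                 covariates=ADJUSTMENT + ("gene",), **opts),
                       f"{analysis}_{name}")
        elif analysis == "sex_specific":
            for sex in ("female", "male"):
                sub = carriers[carriers["sex"] == sex].reset_index(drop=True)
                cov = tuple(c for c in ADJUSTMENT + ("gene",) if c != "sex")
                record(_fit_rows(sub, carrier_inc, analysis=analysis,
                                 group=f"carriers_{sex}", exposure="bmi5",
                                 covariates=cov, **opts), f"{analysis}_{sex}")
        elif analysis == "interactions":
            rows.extend(_interaction_rows(carriers, noncarr, carrier_inc,
                                          pop_inc, config))

    result_rows = pd.DataFrame(rows)
    summaries = summarize_cohort(records)
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True, default=str)
            .encode()).hexdigest(),
        "seed": config.seed,
        "outcome_mode": outcome,
        "verified_only": config.verified_only,
        "weights_recomputed_per_subgroup": True,
        "versions": {"wcohort": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "exclusions": build.exclusions,
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    result = StudyResult(result_rows, build, summaries, weight_tables,
                         manifest, records=records)
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _interaction_rows(carriers, noncarr, carrier_inc, pop_inc, config) -> list:
    """Interaction tests: carrier-status x BMI on the combined cohort,
    sex x BMI and gene x BMI within carriers."""
    opts = dict(ties=config.ties, cluster_correction=config.cluster_correction)
    rows = []

    def try_test(records, spec, term, label):
        base = {"analysis": "interactions", "group": label,
                "term": f"{term[0]} x {term[1]}", "n": len(records),
                "person_years": float(records["exit_age"].sum()),
                "events": int(records["event"].sum()),
                "hr": np.nan, "hr_ci_low": np.nan, "hr_ci_high": np.nan,
                "robust_se": np.nan}
        try:
            stat, df, p, _ = wald_interaction(records, spec, term,
                                              weight_col="weight")
            rows.append({**base, "p": p,
                         "note": f"Wald chi2={stat:.3f}, df={df}"})
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as e:
            rows.append({**base, "p": np.nan, "note": f"not estimable ({e})"})

    md = config.merge_degenerate_strata
    sb = config.weight_stratify_by
    kw = dict(stratify_by=sb, merge_degenerate=md,
              competing_adjust=config.weight_competing_adjust,
              min_stratum_count=config.weight_min_stratum_count)
    if len(carriers) and len(noncarr):
        wc = assign_weights(carriers, compute_weights(
            carriers, carrier_inc, **kw), carrier_inc)
        wn = assign_weights(noncarr, compute_weights(
            noncarr, pop_inc, **kw), pop_inc)
        both = pd.concat([wc, wn], ignore_index=True)
        spec = ModelSpec(exposure="bmi5",
                         covariates=_usable_covariates(both,
                                                       ADJUSTMENT + ("carrier",)),
                         **opts)
        try_test(both, spec, ("carrier", "bmi5"), "all")

    if len(carriers):
        wc = assign_weights(carriers, compute_weights(
            carriers, carrier_inc, **kw), carrier_inc)
        spec = ModelSpec(exposure="bmi5",
                         covariates=_usable_covariates(wc, ADJUSTMENT + ("gene",)),
                         **opts)
        try_test(wc, spec, ("sex", "bmi5"), "carriers")
        if wc["gene"].nunique() > 1:
            try_test(wc, spec, ("gene", "bmi5"), "carriers")
    return rows


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("simulation") is not None:
        d["simulation"] = json.loads(config.simulation.to_json())
    return d


def _write_outputs(result: StudyResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.rows.to_csv(out / "study_rows.tsv", sep="\t", index=False)
    for name, df in result.summaries.items():
        df.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False)
    for key, wt in result.weight_tables.items():
        wt.to_csv(out / f"weights_{key}.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
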