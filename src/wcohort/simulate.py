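"""Synthetic multi-generation family cohorts with proband-driven ascertainment.

Generates pedigrees segregating a rare autosomal-dominant mutation, draws
disease onset ages from piecewise-constant age-specific hazards modified
multiplicatively by covariates, draws competing censoring events, and then
applies the non-random recruitment that real clinic- and registry-based
family studies perform: families enter through an affected proband, so the
retained sample over-represents disease.  Because the generating hazard
ratios are known exactly, every downstream estimator can be validated —
in particular the claim that stratum-calibrated sampling weights remove the
ascertainment bias.

Family structure: each family starts from a founder couple (one founder is a
carrier with probability ``founder_carrier_prob``; the spouse is always a
non-carrier).  Each couple's number of children is Poisson; children marry
non-carrier spouses who are not themselves study subjects, and transmission
is Mendelian (a child of exactly one carrier parent is a carrier with
probability 1/2).  Covariates — body-mass index at age 20, smoking, alcohol,
sex, country — are drawn independently of genotype, so ascertainment is the
only mechanism that can distort the exposure–disease association.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weights import (IncidenceTable, default_carrier_incidence,
                      default_population_incidence)

__all__ = ["SimConfig", "simulate_families", "ascertain", "write_cohort",
           "read_cohort", "AscertainmentError", "substream"]

GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
#: approximate mix of mutated genes among carrier families in large registries
GENE_PROBS = (0.38, 0.49, 0.09, 0.04)
COUNTRY_PROBS = {"ANZ": 0.72, "USA": 0.22, "Canada": 0.06}
#: covariate prevalences (male; ever-smoker and ever-drinker at age 20)
SEX_MALE_P, SMOKE_P, ALCOHOL_P = 0.5, 0.48, 0.65
#: competing censoring causes (polypectomy, other cancers, death as recorded in
#: family registries) are adult phenomena; their hazards start at this age
CENSOR_ONSET_AGE = 20.0
SITE_PROBS = {"right": 0.53, "left": 0.18, "rectosigmoid": 0.04,
              "rectum": 0.12, "unknown": 0.13}

SUBJECT_COLUMNS = [
    "subject_id", "family_id", "carrier", "gene", "sex", "country",
    "height_m", "weight20_kg", "smoke20", "alcohol20",
    "crc_age", "crc_verified", "tumour_site",
    "polypectomy_age", "other_cancer_age", "death_age",
    "last_contact_age", "is_proband",
]


class AscertainmentError(RuntimeError):
    """No family survived the ascertainment filter."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent named random stream derived from one top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) % 2**31,
                               spawn_key=(zlib.crc32(name.encode()),)))


@dataclass
class SimConfig:
    """Generating parameters for a synthetic family cohort.

    Defaults describe a Lynch-syndrome-like study: families conditioned on a
    carrier founder, colorectal-cancer hazards with ~50% carrier cumulative
    risk by 70, BMI at 20 around 22.5 kg/m2 (sd 3.8), ~10% missing body size,
    clinic ascertainment requiring two affected members.
    """

    n_families: int = 300
    founder_carrier_prob: float = 1.0
    offspring_mean: float = 3.0
    generations: int = 3
    carrier_incidence: IncidenceTable = field(default_factory=default_carrier_incidence)
    noncarrier_incidence: IncidenceTable = field(default_factory=default_population_incidence)
    #: log hazard ratio per 5 kg/m2 of BMI at age 20
    beta_bmi5: float = float(np.log(1.30))
    #: log hazard ratios for binary covariates (male, ever-smoker, ever-drinker)
    beta_covariates: dict = field(default_factory=lambda: {
        "sex": 0.0, "smoke20": float(np.log(1.2)), "alcohol20": float(np.log(1.1))})
    bmi_mean: float = 22.5
    bmi_sd: float = 3.8
    #: per-cause censoring rates, events per person-year (hazard starts at
    #: CENSOR_ONSET_AGE; these causes do not occur in childhood)
    censoring_rates: dict = field(default_factory=lambda: {
        "polypectomy": 0.005, "other_cancer": 0.004, "death": 0.0004})
    recruitment_age_range: tuple = (25.0, 75.0)
    ascertainment_mode: str = "clinic"       # "clinic" | "population"
    clinic_min_affected: int = 2
    population_diagnosis_window: float = 5.0
    relative_recruit_prob: float = 0.8
    missing_bmi_prob: float = 0.10
    verified_prob: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {"founder_carrier_prob": self.founder_carrier_prob,
                 "relative_recruit_prob": self.relative_recruit_prob,
                 "missing_bmi_prob": self.missing_bmi_prob,
                 "verified_prob": self.verified_prob}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if any(r < 0 for r in self.censoring_rates.values()):
            raise ValueError("censoring rates must be non-negative")
        if self.bmi_sd <= 0:
            raise ValueError("bmi_sd must be positive")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.ascertainment_mode not in ("clinic", "population"):
            raise ValueError(f"unknown ascertainment_mode {self.ascertainment_mode!r}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("carrier_incidence", "noncarrier_incidence"):
            t = d[key]
            d[key] = {"age_lo": t["age_lo"].tolist(), "age_hi": t["age_hi"].tolist(),
                      "rate": t["rate"].tolist(), "label": t["label"]}
        d["recruitment_age_range"] = list(d["recruitment_age_range"])
        return json.dumps(d, indent=2)


# --- pedigree construction -------------------------------------------------

def _pedigree(config: SimConfig, rng: np.random.Generator):
    """Family id, carrier flag and generation for every subject, in flat arrays."""
    fam, carrier, gen = [], [], []
    for f in range(config.n_families):
        founder_is_carrier = rng.random() < config.founder_carrier_prob
        fam += [f, f]
        carrier += [founder_is_carrier, False]
        gen += [0, 0]
        parents = [founder_is_carrier]          # carrier status of reproducing members
        for g in range(1, config.generations):
            children = []
            for parent_carrier in parents:
                k = rng.poisson(config.offspring_mean)
                inherit = (rng.random(k) < 0.5) & parent_carrier
                children += list(inherit)
            fam += [f] * len(children)
            carrier += children
            gen += [g] * len(children)
            parents = children
    return (np.array(fam, dtype=int), np.array(carrier, dtype=bool),
            np.array(gen, dtype=int))


def simulate_families(config: SimConfig) -> pd.DataFrame:
    """Simulate the complete (pre-ascertainment) population of families.

    Returns one row per subject with genotype, covariates and observable
    event history.  Onset ages follow the piecewise-exponential hazard
    ``rate_g(t) * exp(beta_bmi5*(BMI-22.5)/5 + sum_c beta_c*x_c)`` with
    ``rate_g`` the genotype's incidence table; censoring ages for
    polypectomy, other cancer and death are drawn independently per cause;
    only the earliest event before last contact is retained as history.
    """
    rng = substream(config.seed, "simulate")
    fam, carrier, gen = _pedigree(config, rng)
    n = fam.size

    sex = np.where(rng.random(n) < 1.0 - SEX_MALE_P, "female", "male")
    # founder couples are one of each sex
    founders = gen == 0
    first = np.zeros(n, dtype=bool)
    first[np.searchsorted(fam, np.unique(fam))] = True
    sex[founders & first] = np.where(rng.random(int((founders & first).sum())) < 0.5,
                                     "female", "male")
    spouse = founders & ~first
    sex[spouse] = np.where(sex[np.nonzero(founders & first)[0]] == "female",
                           "male", "female")

    countries = np.array(list(COUNTRY_PROBS))
    country = countries[rng.choice(len(countries), size=config.n_families,
                                   p=list(COUNTRY_PROBS.values()))][fam]
    gene_by_family = np.array(GENES)[rng.choice(len(GENES), size=config.n_families,
                                                p=GENE_PROBS)][fam]
    gene = np.where(carrier, gene_by_family, "none")

    smoke = np.where(rng.random(n) < SMOKE_P, "ever", "never")
    alcohol = np.where(rng.random(n) < ALCOHOL_P, "ever", "never")

    # height/weight generated jointly so BMI hits the target mean/sd
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 14.0, 45.0)
    height = np.where(sex == "male", rng.normal(1.77, 0.07, n),
                      rng.normal(1.63, 0.065, n))
    weight = bmi * height**2

    eta = config.beta_bmi5 * (bmi - 22.5) / 5.0
    x = {"sex": (sex == "male").astype(float),
         "smoke20": (smoke == "ever").astype(float),
         "alcohol20": (alcohol == "ever").astype(float)}
    for name, beta in config.beta_covariates.items():
        if name not in x:
            raise ValueError(f"beta_covariates refers to unknown covariate {name!r}")
        eta += beta * x[name]

    crc = np.where(carrier,
                   config.carrier_incidence.sample_event_ages(eta, rng),
                   config.noncarrier_incidence.sample_event_ages(eta, rng))

    censor = {}
    for cause in ("polypectomy", "other_cancer", "death"):
        rate = config.censoring_rates.get(cause, 0.0)
        censor[cause] = (CENSOR_ONSET_AGE + rng.exponential(1.0 / rate, n)
                         if rate > 0 else np.full(n, np.inf))
    lo, hi = config.recruitment_age_range
    last_contact = rng.uniform(lo, hi, n)

    # keep only the first event in time as observable history
    ages = np.column_stack([crc, censor["polypectomy"], censor["other_cancer"],
                            censor["death"]])
    first_idx = np.argmin(ages, axis=1)
    first_age = ages[np.arange(n), first_idx]
    observed = first_age < last_contact
    cols = {}
    for j, name in enumerate(["crc_age", "polypectomy_age", "other_cancer_age",
                              "death_age"]):
        cols[name] = np.where(observed & (first_idx == j), first_age, np.nan)

    weight = np.where(rng.random(n) < config.missing_bmi_prob, np.nan, weight)
    has_crc = ~np.isnan(cols["crc_age"])
    verified = np.where(has_crc & (rng.random(n) < config.verified_prob),
                        "verified", np.where(has_crc, "self_report", ""))
    sites = np.array(list(SITE_PROBS))
    site = np.where(has_crc, sites[rng.choice(len(sites), n,
                                              p=list(SITE_PROBS.values()))], "")

    df = pd.DataFrame({
        "subject_id": np.arange(n), "family_id": fam,
        "carrier": np.where(carrier, "carrier", "noncarrier"),
        "gene": gene, "sex": sex, "country": country,
        "height_m": height, "weight20_kg": weight,
        "smoke20": smoke, "alcohol20": alcohol,
        "crc_age": cols["crc_age"], "crc_verified": verified,
        "tumour_site": site,
        "polypectomy_age": cols["polypectomy_age"],
        "other_cancer_age": cols["other_cancer_age"],
        "death_age": cols["death_age"],
        "last_contact_age": last_contact,
        "is_proband": False,
    })
    return df[SUBJECT_COLUMNS]


def ascertain(subjects: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Apply proband-driven recruitment to a simulated population.

    ``clinic`` mode keeps families with at least ``clinic_min_affected``
    disease-affected members and marks one affected member as proband;
    ``population`` mode keeps families containing a member diagnosed within
    ``population_diagnosis_window`` years before their last contact (a
    recently diagnosed registry case) and marks that member as proband.
    Non-proband relatives are retained independently with probability
    ``relative_recruit_prob``.  Subject attributes are never altered beyond
    the proband flag.
    """
    rng = substream(config.seed, "ascertain")
    n = len(subjects)
    fam_codes, fams = pd.factorize(subjects["family_id"], sort=True)
    affected = subjects["crc_age"].notna().to_numpy()

    if config.ascertainment_mode == "clinic":
        eligible = affected
        counts = np.bincount(fam_codes, weights=eligible, minlength=len(fams))
        fam_ok = counts >= config.clinic_min_affected
        mark_proband = config.clinic_min_affected >= 1
    else:
        recency = (subjects["last_contact_age"] - subjects["crc_age"]).to_numpy()
        eligible = affected & (recency <= config.population_diagnosis_window)
        counts = np.bincount(fam_codes, weights=eligible, minlength=len(fams))
        fam_ok = counts >= 1
        mark_proband = True

    # one proband per retained family: the eligible member with the largest
    # random key (uniform over eligible members)
    key = np.where(eligible, rng.random(n), -np.inf)
    best = np.full(len(fams), -np.inf)
    np.maximum.at(best, fam_codes, key)
    proband = (eligible & (key == best[fam_codes]) & fam_ok[fam_codes]
               & mark_proband)

    keep = fam_ok[fam_codes] & ((rng.random(n) < config.relative_recruit_prob)
                                | proband)
    if not fam_ok.any():
        raise AscertainmentError(
            f"no family survived ascertainment (mode={config.ascertainment_mode!r}, "
            f"clinic_min_affected={config.clinic_min_affected}, "
            f"population_diagnosis_window={config.population_diagnosis_window}, "
            f"n_families={config.n_families})")
    out = subjects.loc[keep].copy()
    out["is_proband"] = proband[keep]
    return out.reset_index(drop=True)


def marginal_incidence(config: SimConfig, carrier: bool = True,
                       n_mc: int = 200_000) -> IncidenceTable:
    """Population (covariate-averaged) incidence implied by a simulation
    configuration.

    The generator applies covariate effects multiplicatively to a baseline
    table, so the incidence actually experienced by the simulated population
    exceeds the baseline whenever any effect is non-zero.  External reference
    rates in real studies are marginal rates of this kind, and the weighting
    correction is only "correctly specified" when fed them.  The marginal
    survival ``E[exp(-H0(t) * exp(eta))]`` is evaluated by fixed-seed Monte
    Carlo over the generator's covariate distribution and converted back to
    piecewise-constant rates on the baseline's strata.
    """
    base = config.carrier_incidence if carrier else config.noncarrier_incidence
    rng = np.random.default_rng(987654321)   # internal stream, not study randomness
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n_mc), 14.0, 45.0)
    eta = config.beta_bmi5 * (bmi - 22.5) / 5.0
    draws = {"sex": rng.random(n_mc) < SEX_MALE_P,
             "smoke20": rng.random(n_mc) < SMOKE_P,
             "alcohol20": rng.random(n_mc) < ALCOHOL_P}
    for name, beta in config.beta_covariates.items():
        eta += beta * draws[name].astype(float)
    rel = np.exp(eta)
    bounds = np.concatenate([[0.0], base.age_hi])
    H0 = np.asarray(base.cumulative_hazard(bounds))
    S_bar = np.exp(-np.outer(H0, rel)).mean(axis=1)
    H_marg = -np.log(S_bar)
    rates = np.diff(H_marg) / base.widths
    return IncidenceTable(base.age_lo, base.age_hi, rates,
                          label=base.label + "_marginal")


def write_cohort(subjects: pd.DataFrame, path, config: SimConfig | None = None,
                 truth_path=None) -> None:
    """Write the subject table as tab-delimited text (missing ages empty);
    optionally record the generating configuration as a truth sidecar."""
    subjects.to_csv(path, sep="\t", index=False, na_rep="")
    if config is not None and truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write(config.to_json())


def read_cohort(path) -> pd.DataFrame:
    """Read a subject table written by :func:`write_cohort` (or real data in
    the same schema)."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"crc_verified": "string", "tumour_site": "string"})
    for col in ("crc_verified", "tumour_site"):
        df[col] = df[col].fillna("").astype(str)
    return df[SUBJECT_COLUMNS]
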