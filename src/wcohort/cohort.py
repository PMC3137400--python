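"""Exposure definitions, exclusions and censoring: subjects to risk intervals.

Subjects are treated as a cohort from birth.  Time at risk runs from birth to
the first of: colorectal-cancer diagnosis, polypectomy, diagnosis of another
cancer, death, or last contact.  BMI at age 20 is weight at 20 (kg) over
height (m) squared; subjects missing either measurement are excluded (and
counted).  An alternative outcome pools cancer and polyps ("colorectal
neoplasia"), in which case polypectomy no longer censors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["compute_bmi", "who_category", "build_cohort", "WHO_ORDER"]

WHO_ORDER = ["underweight", "normal", "overweight", "obese"]

RECORD_COLUMNS = [
    "subject_id", "family_id", "carrier", "gene", "exit_age", "event",
    "censor_reason", "interview_age", "bmi20", "bmi5", "who_category", "sex",
    "country", "smoke20", "alcohol20", "crc_verified", "tumour_site",
]

# (censoring cause, subject-table age column); order breaks exact age ties
_CENSOR_SOURCES = [
    ("polypectomy", "polypectomy_age"),
    ("other_cancer", "other_cancer_age"),
    ("death", "death_age"),
    ("last_contact", "last_contact_age"),
]


def compute_bmi(weight20_kg, height_m):
    """Body-mass index, kg/m2, from weight (kg) and height (m).

    Raises ``ValueError`` on non-positive input; missing (NaN) values pass
    through so callers can count exclusions.
    """
    w = np.asarray(weight20_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    bad = (w <= 0) | (h <= 0)
    if np.any(bad & ~np.isnan(w) & ~np.isnan(h)):
        idx = np.nonzero(bad)[0] if w.ndim else [0]
        raise ValueError(f"non-positive weight or height at rows {list(idx)[:5]}")
    out = w / h**2
    return out if out.ndim else float(out)


def who_category(bmi20):
    """WHO body-mass category: <=18.49 underweight, 18.50-24.99 normal,
    25.00-29.99 overweight, >=30.00 obese (kg/m2).

    BMI is rounded to two decimals (round-half-even) before the interval
    lookup so the printed category bounds are exhaustive.
    """
    b = np.round(np.asarray(bmi20, dtype=float), 2)
    cat = np.select([b <= 18.49, b < 25.00, b < 30.00],
                    ["underweight", "normal", "overweight"], default="obese")
    return cat if cat.ndim else str(cat)


@dataclass
class BuildResult:
    """Analysis-ready risk intervals plus the exclusion accounting."""
    records: pd.DataFrame
    n_input: int
    n_missing_bmi: int
    n_no_ages: int
    n_unverified_excluded: int = 0

    @property
    def exclusions(self) -> dict:
        return {"n_input": self.n_input, "n_records": len(self.records),
                "n_missing_bmi": self.n_missing_bmi, "n_no_ages": self.n_no_ages,
                "n_unverified_excluded": self.n_unverified_excluded}


def build_cohort(subjects: pd.DataFrame, outcome_mode: str = "crc",
                 verified_only: bool = False) -> BuildResult:
    """Turn a subject table into risk intervals.

    Parameters
    ----------
    subjects : DataFrame
        One row per subject in the schema written by the simulator (the same
        schema is accepted for real data).
    outcome_mode : {"crc", "neoplasia"}
        With ``"crc"`` the event is colorectal cancer and polypectomy
        censors.  With ``"neoplasia"`` the event is the earlier of cancer and
        polypectomy (pooled outcome) and polypectomy no longer censors.
    verified_only : bool
        Drop subjects whose cancer report is self/relative-reported rather
        than verified, before building records.

    Notes
    -----
    Exit age is the minimum over the available event and censoring ages; a
    tie between the event and a censoring cause at the same age counts as an
    event (censoring "at diagnosis" would delete true cases).  Subjects with
    no ages at all are rejected by name.
    """
    if outcome_mode not in ("crc", "neoplasia"):
        raise ValueError(f"unknown outcome_mode {outcome_mode!r}")
    df = subjects.reset_index(drop=True)
    n_input = len(df)

    n_unverified = 0
    if verified_only:
        drop = df["crc_age"].notna() & (df["crc_verified"] == "self_report")
        n_unverified = int(drop.sum())
        df = df[~drop].reset_index(drop=True)

    age_cols = ["crc_age"] + [c for _, c in _CENSOR_SOURCES]
    no_ages = df[age_cols].isna().all(axis=1)
    if no_ages.any():
        raise ValueError("subjects with no event or censoring ages: "
                         f"{df.loc[no_ages, 'subject_id'].tolist()[:5]}")
    n_no_ages = 0

    bmi_ok = df["height_m"].notna() & df["weight20_kg"].notna()
    n_missing_bmi = int((~bmi_ok).sum())
    df = df[bmi_ok].reset_index(drop=True)

    if outcome_mode == "crc":
        event_age = df["crc_age"].to_numpy()
        censor_sources = _CENSOR_SOURCES
    else:
        event_age = np.fmin(df["crc_age"].to_numpy(),
                            df["polypectomy_age"].to_numpy())
        censor_sources = [s for s in _CENSOR_SOURCES if s[0] != "polypectomy"]

    censor_ages = np.column_stack([df[c].to_numpy() for _, c in censor_sources])
    with np.errstate(invalid="ignore"):
        min_censor_idx = np.nanargmin(np.where(np.isnan(censor_ages), np.inf,
                                               censor_ages), axis=1)
    min_censor = censor_ages[np.arange(len(df)), min_censor_idx]
    ev_age = np.where(np.isnan(event_age), np.inf, event_age)
    event = ev_age <= min_censor            # tie: event wins
    exit_age = np.where(event, ev_age, min_censor)
    reason = np.where(event, "none",
                      np.array([r for r, _ in censor_sources])[min_censor_idx])

    bmi = compute_bmi(df["weight20_kg"], df["height_m"])
    records = pd.DataFrame({
        "subject_id": df["subject_id"], "family_id": df["family_id"],
        "carrier": df["carrier"], "gene": df["gene"],
        "exit_age": exit_age, "event": event.astype(int),
        "censor_reason": reason,
        "interview_age": df["last_contact_age"],
        "bmi20": bmi, "bmi5": bmi / 5.0, "who_category": who_category(bmi),
        "sex": df["sex"], "country": df["country"],
        "smoke20": df["smoke20"], "alcohol20": df["alcohol20"],
        "crc_verified": df["crc_verified"], "tumour_site": df["tumour_site"],
    })[RECORD_COLUMNS]
    return BuildResult(records, n_input, n_missing_bmi, n_no_ages, n_unverified)
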