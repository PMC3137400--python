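"""Ascertainment correction by age-stratum sampling weights.

Family cohorts recruited through affected probands over-represent diseased
subjects at every age.  The weighted-cohort correction compares, within each
age stratum, the sampled proportion of affected subjects with the proportion
expected from external age-specific incidence rates, and weights affected and
unaffected subjects so that the weighted affected proportion in each stratum
equals the external expectation.  Weighted proportional-hazards fits on the
reweighted sample are then approximately free of the ascertainment bias,
provided the external rates are correctly specified.

Two rate sources are used: previously published age-specific incidence for
mutation carriers, and general-population incidence for non-carriers (carriers
being too rare for their presence to perturb population rates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceTable",
    "WeightTable",
    "expected_affected_proportion",
    "compute_weights",
    "attach_noncarrier_weights",
    "assign_weights",
    "default_carrier_incidence",
    "default_population_incidence",
]


@dataclass(frozen=True)
class IncidenceTable:
    """Piecewise-constant age-specific incidence, events per person-year.

    Strata are half-open intervals ``(age_lo, age_hi]`` that must tile the
    age axis contiguously from 0.  The final stratum is treated as open-ended
    when assigning subjects, but the rate beyond ``age_hi[-1]`` is taken as 0
    when simulating (no events are generated past the table's support).

    Parameters
    ----------
    age_lo, age_hi : array-like of float
        Stratum bounds in years.
    rate : array-like of float
        Incidence rate per person-year within each stratum.
    label : str
        Group the rates describe (e.g. ``"carrier"`` or ``"population"``).
    """

    age_lo: np.ndarray
    age_hi: np.ndarray
    rate: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        lo = np.asarray(self.age_lo, dtype=float)
        hi = np.asarray(self.age_hi, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        if not (lo.shape == hi.shape == rate.shape) or lo.ndim != 1 or lo.size == 0:
            raise ValueError("age_lo, age_hi and rate must be equal-length 1-d arrays")
        if lo[0] != 0.0:
            raise ValueError(f"incidence table '{self.label}': strata must start at age 0")
        if not np.all(hi > lo):
            raise ValueError(f"incidence table '{self.label}': empty or inverted stratum")
        if not np.allclose(lo[1:], hi[:-1]):
            raise ValueError(f"incidence table '{self.label}': strata must be contiguous")
        if np.any(rate < 0):
            raise ValueError(f"incidence table '{self.label}': negative rate")
        object.__setattr__(self, "age_lo", lo)
        object.__setattr__(self, "age_hi", hi)
        object.__setattr__(self, "rate", rate)

    def __len__(self) -> int:
        return self.age_lo.size

    @property
    def widths(self) -> np.ndarray:
        return self.age_hi - self.age_lo

    def cumulative_hazard(self, age) -> np.ndarray | float:
        """Integral of the rate from 0 to ``age`` (constant past the table end)."""
        age = np.asarray(age, dtype=float)
        exposure = np.clip(age[..., None] - self.age_lo, 0.0, self.widths)
        out = exposure @ self.rate
        return out if out.ndim else float(out)

    def cumulative_incidence(self, age) -> np.ndarray | float:
        """1 - exp(-cumulative hazard), the net probability of disease by ``age``."""
        return 1.0 - np.exp(-self.cumulative_hazard(age))

    def stratum_of(self, age) -> np.ndarray:
        """Index of the stratum ``(lo, hi]`` containing each age; the last
        stratum is open-ended upward, ages at 0 map to the first stratum."""
        idx = np.searchsorted(self.age_lo, np.asarray(age, dtype=float), side="left") - 1
        return np.clip(idx, 0, len(self) - 1)

    def sample_event_ages(self, log_relative_hazard, rng: np.random.Generator) -> np.ndarray:
        """Draw event ages by inversion of the piecewise-exponential hazard.

        Each subject's hazard is ``rate(t) * exp(log_relative_hazard)``.
        Subjects whose cumulative hazard never reaches the drawn exponential
        deviate get ``inf`` (no event within the table's support).
        """
        eta = np.asarray(log_relative_hazard, dtype=float)
        grid = np.concatenate([[0.0], np.cumsum(self.rate * self.widths)])
        target = rng.exponential(size=eta.shape) / np.exp(eta)
        j = np.clip(np.searchsorted(grid, target, side="right") - 1, 0, len(self) - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ages = self.age_lo[j] + (target - grid[j]) / self.rate[j]
        return np.where(target >= grid[-1], np.inf, ages)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "IncidenceTable":
        """Read a delimited table with columns ``age_lo``, ``age_hi``, ``rate``."""
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df["age_lo"].to_numpy(), df["age_hi"].to_numpy(),
                   df["rate"].to_numpy(), label=label)

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_lo": self.age_lo, "age_hi": self.age_hi,
                      "rate": self.rate}).to_csv(path, sep="\t", index=False)


def censoring_survival(records: pd.DataFrame,
                       competing=("polypectomy", "other_cancer", "death")):
    """Nelson-Aalen survival from competing censoring causes.

    Estimates the probability of remaining free of polypectomy, other-cancer
    and death censoring by each age, treating those censor reasons as events
    and everything else (disease, last contact) as censoring.  Because these
    censoring hazards are shared by affected and unaffected subjects, the
    estimate is valid even on an ascertained (disease-enriched) sample.

    Returns ``(times, surv)`` describing the right-continuous step function,
    with ``surv[j]`` the survival from ``times[j]`` onward.
    """
    t = records["exit_age"].to_numpy(dtype=float)
    e = records["censor_reason"].isin(competing).to_numpy()
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    n = ts.size
    times, d = np.unique(ts[es], return_counts=True)
    if times.size == 0:
        return np.array([0.0]), np.array([1.0])
    at_risk = n - np.searchsorted(ts, times, side="left")
    haz = d / at_risk
    surv = np.exp(-np.cumsum(haz))
    return times, surv


def _surv_at(times: np.ndarray, surv: np.ndarray, age) -> np.ndarray:
    """Evaluate the censoring-survival step function at given ages."""
    idx = np.searchsorted(times, np.asarray(age, dtype=float), side="right") - 1
    out = np.where(idx >= 0, surv[np.clip(idx, 0, surv.size - 1)], 1.0)
    return out


def expected_affected_proportion(table: IncidenceTable, k: int,
                                 censoring=None) -> float:
    """Expected proportion affected among subjects of the population whose
    classification age falls in stratum ``k``.

    Without censoring information this is the net cumulative incidence by the
    stratum's upper bound, ``p_k = 1 - exp(-sum_{j<=k} rate_j * width_j)``.
    With ``censoring=(times, surv)`` — survival from competing censoring
    causes, see :func:`censoring_survival` — it is the *observable* cumulative
    incidence ``p_k = int_0^{hi_k} S_c(u) exp(-H(u)) dH(u)``: a diagnosis
    only enters a study's records if it precedes polypectomy, another cancer
    and death, so calibrating to the net incidence would demand more affected
    subjects than the population can show.
    """
    if not 0 <= k < len(table):
        raise IndexError(f"stratum {k} outside table with {len(table)} strata")
    hi = table.age_hi[k]
    if censoring is None:
        return float(1.0 - np.exp(-float(table.cumulative_hazard(hi))))
    times, surv = censoring
    # integrate S_c(u) d[1 - exp(-H(u))] exactly on cells where both the rate
    # and the censoring-survival step are constant
    cuts = np.unique(np.concatenate(
        [[0.0, hi], table.age_hi[table.age_hi < hi],
         times[(times > 0) & (times < hi)]]))
    F = 1.0 - np.exp(-np.asarray(table.cumulative_hazard(cuts)))
    sc = _surv_at(times, surv, cuts[:-1])           # value on [cut_j, cut_j+1)
    return float(np.sum(sc * np.diff(F)))


@dataclass
class WeightTable:
    """Per-stratum sampling weights for affected and unaffected subjects.

    ``table`` holds one row per stratum: the pooled ``group`` the stratum
    belongs to (sparse strata are pooled upward), observed counts ``n`` and
    ``d`` (subjects, affected subjects) of that group, the expected affected
    proportion ``p``, the two weights, and a ``fallback`` marker for
    degenerate groups where the defining formulas are undefined (``d == 0``
    or ``d == n``).

    On every non-degenerate group the weights satisfy
    ``d*w_affected + (n-d)*w_unaffected == n`` (mean weight one) and
    ``d*w_affected / n == p`` (weighted affected proportion calibrated).
    """

    table: pd.DataFrame
    label: str = ""
    stratify_by: str = "interview"

    def weight_for(self, records: pd.DataFrame, incidence: IncidenceTable) -> np.ndarray:
        """Per-record weights, by the stratum of each record's classification
        age (interview or exit age, per ``stratify_by``)."""
        k = incidence.stratum_of(_class_age(records, self.stratify_by))
        w_aff = self.table["w_affected"].to_numpy()[k]
        w_un = self.table["w_unaffected"].to_numpy()[k]
        return np.where(records["event"].to_numpy() == 1, w_aff, w_un)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _class_age(records: pd.DataFrame, stratify_by: str) -> np.ndarray:
    if stratify_by == "interview":
        col = "interview_age" if "interview_age" in records.columns else "exit_age"
        return records[col].to_numpy()
    if stratify_by == "exit":
        return records["exit_age"].to_numpy()
    raise ValueError(f"unknown stratify_by {stratify_by!r}")


def compute_weights(records: pd.DataFrame, table: IncidenceTable, *,
                    stratify_by: str = "interview",
                    competing_adjust: bool = True,
                    min_stratum_count: int = 0,
                    merge_degenerate: bool = False) -> WeightTable:
    """Sampling weights making each stratum's weighted affected proportion
    equal its external expectation.

    For stratum ``k`` with ``n_k`` subjects of whom ``d_k`` are affected and
    expected affected proportion ``p_k``::

        w_affected_k   = p_k * n_k / d_k
        w_unaffected_k = (1 - p_k) * n_k / (n_k - d_k)

    A positive ``min_stratum_count`` pools adjacent strata upward until each
    pooled group holds at least that many affected and unaffected subjects
    (the pool takes the expected proportion of its oldest member) — an
    optional stabilisation for sparse data; the default (0) keeps the raw
    per-stratum construction.  Groups that remain degenerate fall back to
    unit weights (flagged): with ``d == 0`` both weights are 1; with
    ``d == n`` the affected weight is 1.  ``merge_degenerate`` pools exactly
    the degenerate strata.

    With ``competing_adjust`` (default) the expectation ``p_k`` is the
    observable cumulative incidence: the external rates are discounted by the
    sample-estimated survival from competing censoring causes (polypectomy,
    other cancer, death), since diagnoses pre-empted by those events never
    appear in a cohort's records.  Disable it to calibrate against the plain
    net cumulative incidence.

    ``stratify_by`` selects the classification age: ``"interview"`` (default)
    strata subjects by age at last contact, so that ``p_k`` — the cumulative
    incidence by the stratum bound — matches what a population member of that
    current age would have experienced; ``"exit"`` strata by age at event or
    censoring.  The interview-age choice is the one under which the
    calibration argument is self-consistent: among population members
    interviewed at age a, the proportion already diagnosed is the cumulative
    incidence near a, whereas the affected proportion among subjects *exiting*
    in an age stratum depends strongly on the censoring distribution and is
    far from the cumulative incidence.

    Raises
    ------
    ValueError
        If ``p_k == 1`` while unaffected subjects are present in stratum
        ``k`` — the external table asserts certain disease yet the sample
        contains survivors, so no finite calibrating weight exists.
    """
    k = table.stratum_of(_class_age(records, stratify_by))
    ev = records["event"].to_numpy().astype(int)
    nk = np.bincount(k, minlength=len(table)).astype(float)
    dk = np.bincount(k, weights=ev, minlength=len(table)).astype(float)
    cens = (censoring_survival(records)
            if competing_adjust and "censor_reason" in records.columns else None)
    pk = np.array([expected_affected_proportion(table, j, censoring=cens)
                   for j in range(len(table))])

    bad = (pk >= 1.0) & (dk < nk)
    if np.any(bad):
        j = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"incidence table '{table.label}' implies certain disease by stratum {j} "
            f"(p=1) but unaffected subjects were observed there")

    # pool sparse strata upward so every group supports stable fractions
    K = len(table)
    threshold = max(min_stratum_count, 1 if merge_degenerate else 0)
    group = np.arange(K)
    if threshold > 0:
        n_acc, d_acc, start = 0.0, 0.0, 0
        for j in range(K):
            n_acc += nk[j]
            d_acc += dk[j]
            sparse = d_acc < threshold or (n_acc - d_acc) < threshold
            if not sparse or j == K - 1:
                group[start: j + 1] = j
                n_acc, d_acc, start = 0.0, 0.0, j + 1
        nk = np.bincount(group, weights=nk, minlength=K)[group]
        dk = np.bincount(group, weights=dk, minlength=K)[group]
        pk = pk[group]

    w_aff = np.ones(K)
    w_un = np.ones(K)
    fallback = np.full(K, "", dtype=object)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (dk > 0) & (dk < nk)
        w_aff[ok] = pk[ok] * nk[ok] / dk[ok]
        w_un[ok] = (1.0 - pk[ok]) * nk[ok] / (nk[ok] - dk[ok])
    fallback[(nk > 0) & (dk == 0)] = "no_affected"
    fallback[(nk > 0) & (dk == nk)] = "all_affected"
    fallback[nk == 0] = "empty"

    return WeightTable(
        table=pd.DataFrame({
            "stratum": np.arange(K), "group": group,
            "age_lo": table.age_lo, "age_hi": table.age_hi,
            "n": nk, "d": dk, "p": pk,
            "w_affected": w_aff, "w_unaffected": w_un,
            "fallback": fallback,
        }),
        label=table.label,
        stratify_by=stratify_by,
    )


def attach_noncarrier_weights(records: pd.DataFrame,
                              population_table: IncidenceTable, *,
                              stratify_by: str = "interview",
                              competing_adjust: bool = True,
                              min_stratum_count: int = 0,
                              merge_degenerate: bool = False) -> WeightTable:
    """Weights for non-carriers, using general-population incidence.

    Mutations are rare enough that non-carrier incidence is taken to equal
    the general-population rates; the construction is otherwise identical to
    :func:`compute_weights`.
    """
    return compute_weights(records, population_table, stratify_by=stratify_by,
                           competing_adjust=competing_adjust,
                           min_stratum_count=min_stratum_count,
                           merge_degenerate=merge_degenerate)


def assign_weights(records: pd.DataFrame, wt: WeightTable,
                   incidence: IncidenceTable) -> pd.DataFrame:
    """Copy of ``records`` with a ``weight`` column from the weight table."""
    out = records.copy()
    out["weight"] = wt.weight_for(records, incidence)
    return out


def _five_year(rates_by_age: dict[int, float], label: str) -> IncidenceTable:
    ages = sorted(rates_by_age)
    lo = np.array(ages, dtype=float)
    return IncidenceTable(lo, lo + 5.0, np.array([rates_by_age[a] for a in ages]),
                          label=label)


def default_carrier_incidence() -> IncidenceTable:
    """Illustrative age-specific colorectal-cancer incidence for mismatch-repair
    mutation carriers (per person-year, 5-year strata).

    Shaped like published penetrance estimates for Lynch syndrome — negligible
    before age 20, rising steeply through mid-life, cumulative risk to age 70
    of roughly 50%.  Intended as a simulation and demonstration default; real
    analyses should supply externally estimated rates.
    """
    return _five_year({
        0: 0.0, 5: 0.0, 10: 0.0, 15: 0.0002,
        20: 0.001, 25: 0.003, 30: 0.006, 35: 0.010,
        40: 0.014, 45: 0.018, 50: 0.020, 55: 0.022,
        60: 0.024, 65: 0.025, 70: 0.025, 75: 0.025,
    }, label="carrier")


def default_population_incidence() -> IncidenceTable:
    """Illustrative general-population colorectal-cancer incidence (per
    person-year, 5-year strata), with the familiar late-life rise and a
    lifetime risk of about 6%."""
    return _five_year({
        0: 0.0, 5: 0.0, 10: 0.0, 15: 0.0,
        20: 0.00001, 25: 0.00002, 30: 0.00005, 35: 0.0001,
        40: 0.0002, 45: 0.0004, 50: 0.0007, 55: 0.0012,
        60: 0.0018, 65: 0.0025, 70: 0.0033, 75: 0.0040,
    }, label="population")
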