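"""Weighted Cox proportional-hazards regression with age as the time scale.

Implements the weighted partial likelihood from first principles: Newton-
Raphson with step-halving on

    l(beta) = sum_events w_i [x_i beta - log sum_{j in R(t_i)} w_j exp(x_j beta)]

(Breslow ties; Efron available), risk sets defined on age with entry at
birth, external per-subject sampling weights, a Huber-White sandwich
variance with score residuals aggregated within families before the outer
product, scaled-Schoenfeld proportional-hazards diagnostics, and robust Wald
tests for interaction terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ModelSpec", "CoxFit", "ConvergenceError", "fit",
           "robust_variance", "schoenfeld_test", "wald_interaction",
           "build_design"]

_BINARY_LEVELS = {"sex": ("female", "male"), "smoke20": ("never", "ever"),
                  "alcohol20": ("never", "ever"),
                  "carrier": ("noncarrier", "carrier")}


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed; carries the log-likelihood trace and a
    separation flag."""

    def __init__(self, message: str, trace=None, separation: bool = False):
        super().__init__(message)
        self.trace = list(trace or [])
        self.separation = separation


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: exposure term, adjustment covariates, interactions.

    ``exposure`` is ``"bmi5"`` (continuous, per 5 kg/m2 so exp(beta) is the
    reported hazard-ratio unit), ``"who_category"`` (indicator contrasts
    against normal weight) or ``"custom"`` (the columns named in
    ``exposure_cols`` enter as-is — used for fractional-polynomial terms).
    ``covariates`` may include sex, country, smoke20, alcohol20, gene,
    carrier, or any numeric column.  ``interactions`` are unordered pairs of
    included terms, encoded as products of their design columns.
    """

    exposure: str = "bmi5"
    exposure_cols: tuple = ()
    covariates: tuple = ()
    interactions: tuple = ()
    ties: str = "breslow"           # "breslow" | "efron"
    tol: float = 1e-9
    max_iter: int = 50
    cluster_correction: bool = False

    def __post_init__(self):
        if self.exposure not in ("bmi5", "who_category", "custom"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.exposure == "custom" and not self.exposure_cols:
            raise ValueError("custom exposure needs exposure_cols")
        if self.ties not in ("breslow", "efron"):
            raise ValueError(f"unknown ties method {self.ties!r}")
        for a, b in self.interactions:
            terms = (self.exposure,) + tuple(self.covariates)
            for t in (a, b):
                if t not in terms and t != "bmi5":
                    raise ValueError(f"interaction term {t!r} not in the model")


def _encode(records: pd.DataFrame, name: str) -> pd.DataFrame:
    """Design columns for one model term (reference levels fixed)."""
    if name == "bmi5":
        return records[["bmi5"]].astype(float)
    if name == "who_category":
        cats = [c for c in ("underweight", "overweight", "obese")
                if (records["who_category"] == c).any()]
        return pd.DataFrame({f"who_{c}": (records["who_category"] == c).astype(float)
                             for c in cats}, index=records.index)
    if name in _BINARY_LEVELS:
        ref, other = _BINARY_LEVELS[name]
        return pd.DataFrame({name: (records[name] == other).astype(float)},
                            index=records.index)
    if name in ("country", "gene"):
        levels = sorted(records[name].unique())
        return pd.DataFrame({f"{name}_{lev}": (records[name] == lev).astype(float)
                             for lev in levels[1:]}, index=records.index)
    if name in records.columns and pd.api.types.is_numeric_dtype(records[name]):
        return records[[name]].astype(float)
    raise ValueError(f"cannot encode model term {name!r}")


def build_design(records: pd.DataFrame, spec: ModelSpec):
    """Design matrix for a model spec.

    Returns ``(X, groups)`` where ``X`` is a float DataFrame and ``groups``
    maps each model term to its column names (used for multi-column Wald
    tests).
    """
    groups: dict[str, list[str]] = {}
    parts = []
    if spec.exposure == "custom":
        block = records[list(spec.exposure_cols)].astype(float)
    else:
        block = _encode(records, spec.exposure)
    parts.append(block)
    groups[spec.exposure if spec.exposure != "custom" else "exposure"] = \
        list(block.columns)
    for cov in spec.covariates:
        block = _encode(records, cov)
        parts.append(block)
        groups[cov] = list(block.columns)
    for a, b in spec.interactions:
        a, b = sorted((a, b))
        cols_a = _encode(records, a) if a != spec.exposure else parts[0]
        cols_b = _encode(records, b) if b != spec.exposure else parts[0]
        inter = {}
        for ca in cols_a.columns:
            for cb in cols_b.columns:
                inter[f"{ca}:{cb}"] = cols_a[ca] * cols_b[cb]
        block = pd.DataFrame(inter, index=records.index)
        parts.append(block)
        groups[f"{a}:{b}"] = list(block.columns)
    X = pd.concat(parts, axis=1)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"covariates constant across all subjects: {const}")
    return X, groups


# --- partial-likelihood machinery ------------------------------------------

class _Sorted:
    """Inputs sorted by exit age, with tie-group bookkeeping."""

    def __init__(self, X, time, event, w):
        order = np.argsort(time, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.t = time[order]
        self.d = event[order].astype(float)
        self.w = w[order]
        n = self.t.size
        new = np.r_[True, self.t[1:] != self.t[:-1]]
        self.grp_first = np.maximum.accumulate(np.where(new, np.arange(n), 0))
        last = np.r_[new[1:], True]
        rev = np.minimum.accumulate(np.where(last, np.arange(n), n - 1)[::-1])[::-1]
        self.grp_last = rev
        self.order = order


def _loglik_parts(beta, s: _Sorted, ties: str):
    """Weighted partial log-likelihood, gradient and negative Hessian."""
    n, p = s.X.shape
    eta = s.X @ beta
    r = s.w * np.exp(eta)
    rx = r[:, None] * s.X
    rxx = rx[:, :, None] * s.X[:, None, :]
    S0 = np.cumsum(r[::-1])[::-1][s.grp_first]
    S1 = np.cumsum(rx[::-1], axis=0)[::-1][s.grp_first]
    S2 = np.cumsum(rxx[::-1], axis=0)[::-1][s.grp_first]

    ev = s.d > 0
    wv = s.w[ev]
    if ties == "breslow" or not _has_tied_events(s):
        xbar = S1[ev] / S0[ev, None]
        ll = float(np.sum(wv * (eta[ev] - np.log(S0[ev]))))
        grad = (wv[:, None] * (s.X[ev] - xbar)).sum(axis=0)
        V = S2[ev] / S0[ev, None, None] - xbar[:, :, None] * xbar[:, None, :]
        info = (wv[:, None, None] * V).sum(axis=0)
        return ll, grad, info
    return _efron_parts(beta, s, eta, r, rx, rxx, S0, S1, S2)


def _has_tied_events(s: _Sorted) -> bool:
    ev_idx = np.nonzero(s.d > 0)[0]
    return np.unique(s.grp_first[ev_idx]).size < ev_idx.size


def _efron_parts(beta, s, eta, r, rx, rxx, S0, S1, S2):
    """Efron tie handling: within a tie group the event mass is removed in
    equal fractions l/m from the risk-set sums, each fraction carrying the
    group's mean event weight."""
    p = s.X.shape[1]
    ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
    ev_idx = np.nonzero(s.d > 0)[0]
    for g in np.unique(s.grp_first[ev_idx]):
        members = ev_idx[s.grp_first[ev_idx] == g]
        m = members.size
        wD = s.w[members]
        sD0 = r[members].sum()
        sD1 = rx[members].sum(axis=0)
        sD2 = rxx[members].sum(axis=0)
        wbar = wD.mean()
        ll += float(np.sum(wD * eta[members]))
        grad += (wD[:, None] * s.X[members]).sum(axis=0)
        for l in range(m):
            f = l / m
            d0 = S0[g] - f * sD0
            xbar = (S1[g] - f * sD1) / d0
            ll -= wbar * np.log(d0)
            grad -= wbar * xbar
            info += wbar * ((S2[g] - f * sD2) / d0 - np.outer(xbar, xbar))
    return ll, grad, info


def _newton(X, time, event, w, ties, tol, max_iter):
    s = _Sorted(X, time, event, w)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _loglik_parts(beta, s, ties)
    trace = [ll]
    converged = False
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular information matrix: {e}",
                                   trace=trace) from e
        # step-halving: never accept a decrease in the partial log-likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _loglik_parts(cand, s, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            raise ConvergenceError("step-halving failed to find an uphill step",
                                   trace=trace)
        delta = cand - beta
        beta, ll_old, ll = cand, ll, ll_new
        grad, info = grad_new, info_new
        trace.append(ll)
        if np.max(np.abs(beta)) > 40:
            raise ConvergenceError(
                "coefficient diverging (|beta| > 40): likely separation "
                "(monotone likelihood)", trace=trace, separation=True)
        if (abs(ll - ll_old) < tol * (abs(ll_old) + 1.0)
                or np.max(np.abs(delta)) < 1e-8):
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations",
                               trace=trace)
    # a converged fit with an extreme linear-predictor spread means the
    # likelihood is effectively monotone (quasi-separation): the reported
    # maximum is an artefact of the stopping rule, not a finite MLE
    if np.ptp(s.X @ beta) > 20:
        raise ConvergenceError(
            "extreme linear-predictor spread at convergence: separation "
            "(monotone likelihood)", trace=trace, separation=True)
    return beta, ll, info, it, trace, s


def _score_residuals(beta, s: _Sorted, ties: str) -> np.ndarray:
    """Per-subject weighted score residuals (Breslow baseline), in the sorted
    order of ``s``.  They sum to the score, i.e. to ~0 at the MLE."""
    n, p = s.X.shape
    eta = s.X @ beta
    r = s.w * np.exp(eta)
    S0 = np.cumsum(r[::-1])[::-1][s.grp_first]
    S1 = np.cumsum((r[:, None] * s.X)[::-1], axis=0)[::-1][s.grp_first]
    xbar = S1 / S0[:, None]
    inc0 = np.where(s.d > 0, s.w / S0, 0.0)
    inc1 = inc0[:, None] * xbar
    C0 = np.cumsum(inc0)[s.grp_last]
    C1 = np.cumsum(inc1, axis=0)[s.grp_last]
    U = (s.d * s.w)[:, None] * (s.X - xbar)
    U -= (s.w * np.exp(eta))[:, None] * (s.X * C0[:, None] - C1)
    return U


@dataclass
class CoxFit:
    """A fitted weighted Cox model.

    Holds coefficients, the naive (inverse-information) and family-clustered
    sandwich covariances, the weighted partial log-likelihood, Schoenfeld
    residuals at event ages, and convergence metadata.  ``summary()`` gives
    the reporting table: hazard ratios with robust 95% confidence intervals
    and two-sided Wald p-values.
    """

    params: pd.Series
    naive_cov: pd.DataFrame
    robust_cov: pd.DataFrame
    loglik: float
    n: int
    n_events: int
    iterations: int
    converged: bool
    schoenfeld: pd.DataFrame
    groups: dict
    spec: ModelSpec
    score_residuals: pd.DataFrame = field(repr=False, default=None)
    cluster: pd.Series = field(repr=False, default=None)
    trace: list = field(repr=False, default_factory=list)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.robust_cov)),
                         index=self.params.index)

    def summary(self) -> pd.DataFrame:
        se = self.robust_se
        z = self.params / se
        return pd.DataFrame({
            "coef": self.params, "hr": np.exp(self.params), "robust_se": se,
            "hr_ci_low": np.exp(self.params - 1.959963984540054 * se),
            "hr_ci_high": np.exp(self.params + 1.959963984540054 * se),
            "z": z, "p": 2.0 * stats.norm.sf(np.abs(z)),
        })

    def wald_test(self, terms) -> tuple[float, int, float]:
        """Robust Wald test that all coefficients of the named model term(s)
        are zero.  Returns (chi-square statistic, df, p)."""
        cols = []
        for t in np.atleast_1d(terms):
            cols += self.groups[t]
        idx = [self.params.index.get_loc(c) for c in cols]
        b = self.params.to_numpy()[idx]
        V = self.robust_cov.to_numpy()[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        return stat, len(idx), float(stats.chi2.sf(stat, len(idx)))


def fit(records: pd.DataFrame, spec: ModelSpec, weight_col: str | None = None,
        cluster_col: str = "family_id") -> CoxFit:
    """Fit the weighted Cox model defined by ``spec`` on risk-interval records.

    ``records`` must carry ``exit_age``, ``event`` and the model's columns;
    ``weight_col`` names the sampling-weight column (unit weights if None).
    Robust variance clusters on ``cluster_col``.
    """
    X, groups = build_design(records, spec)
    time = records["exit_age"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    if np.unique(time[event == 1]).size < 2:
        raise ValueError("need at least 2 distinct event ages")
    w = (records[weight_col].to_numpy(dtype=float) if weight_col
         else np.ones(len(records)))
    if np.any(w < 0):
        raise ValueError("negative weights")

    names = list(X.columns)
    beta, ll, info, it, trace, s = _newton(
        X.to_numpy(dtype=float), time, event, w, spec.ties, spec.tol,
        spec.max_iter)

    naive = np.linalg.inv(info)
    U = _score_residuals(beta, s, spec.ties)
    clusters = records[cluster_col].to_numpy()[s.order]
    resid = pd.DataFrame(U, columns=names)
    resid[cluster_col] = clusters

    # Schoenfeld residuals at each event, on the original (unscaled) scale
    eta = s.X @ beta
    r = s.w * np.exp(eta)
    S0 = np.cumsum(r[::-1])[::-1][s.grp_first]
    S1 = np.cumsum((r[:, None] * s.X)[::-1], axis=0)[::-1][s.grp_first]
    ev = s.d > 0
    sch = pd.DataFrame(s.X[ev] - (S1 / S0[:, None])[ev], columns=names)
    sch.insert(0, "event_age", s.t[ev])
    sch.insert(1, "weight", s.w[ev])

    fit_ = CoxFit(
        params=pd.Series(beta, index=names),
        naive_cov=pd.DataFrame(naive, index=names, columns=names),
        robust_cov=None, loglik=ll, n=len(records),
        n_events=int(event.sum()), iterations=it, converged=True,
        schoenfeld=sch, groups=groups, spec=spec,
        score_residuals=resid, cluster=pd.Series(clusters, name=cluster_col),
        trace=trace)
    fit_.robust_cov = robust_variance(fit_)
    return fit_


def robust_variance(fit_: CoxFit, cluster: pd.Series | None = None) -> pd.DataFrame:
    """Huber-White sandwich covariance A^-1 B A^-1, with the weighted score
    residuals summed within each cluster (family) before the outer product.

    With one subject per cluster and unit weights this is the standard
    model-robust (Lin-Wei) sandwich.  An optional g/(g-1) small-cluster
    correction is applied when the model spec requests it.
    """
    names = list(fit_.params.index)
    resid = fit_.score_residuals
    key = cluster if cluster is not None else resid.iloc[:, -1]
    Uc = resid[names].groupby(np.asarray(key)).sum().to_numpy()
    B = Uc.T @ Uc
    A_inv = fit_.naive_cov.to_numpy()
    V = A_inv @ B @ A_inv
    if fit_.spec.cluster_correction:
        g = Uc.shape[0]
        V = V * g / (g - 1)
    return pd.DataFrame(V, index=names, columns=names)


def schoenfeld_test(fit_: CoxFit, transform=None) -> pd.DataFrame:
    """Proportional-hazards score test from scaled Schoenfeld residuals.

    Regresses the scaled Schoenfeld residuals on (a transform of) event age
    and tests zero slope per covariate, after Grambsch-Therneau with the
    average risk-set covariance approximated by the information matrix.
    Returns one row per covariate with the chi-square statistic and p.
    """
    sch = fit_.schoenfeld
    names = list(fit_.params.index)
    if len(sch) < 10:
        raise ValueError("PH test needs at least 10 events")
    if len(sch) <= len(names):
        raise ValueError("fewer events than covariates")
    g = sch["event_age"].to_numpy() if transform is None \
        else transform(sch["event_age"].to_numpy())
    w = sch["weight"].to_numpy()
    W = w.sum()
    gbar = float(np.sum(w * g) / W)
    S = sch[names].to_numpy()
    num = (w * (g - gbar)) @ S
    A = np.linalg.inv(fit_.naive_cov.to_numpy())
    # Var(sum w_k (g_k - gbar) s_k) ~ sum w_k^2 (g_k - gbar)^2 * Vbar with the
    # average risk-set covariance Vbar = A / (sum of event weights)
    denom = float(np.sum(w**2 * (g - gbar) ** 2)) / W * np.diag(A)
    stat = num**2 / denom
    return pd.DataFrame({"chi2": stat, "df": 1,
                         "p": stats.chi2.sf(stat, 1)}, index=names)


def wald_interaction(records: pd.DataFrame, spec: ModelSpec, term,
                     weight_col: str | None = None,
                     cluster_col: str = "family_id"):
    """Robust Wald test of an interaction: refits with the product term added
    and tests its coefficients against zero.

    Returns ``(statistic, df, p, fit)``; symmetric in the pair order.
    """
    a, b = sorted(term)
    for t in (a, b):
        if t != spec.exposure and t not in spec.covariates:
            raise ValueError(f"main effect {t!r} missing from the model")
    spec2 = ModelSpec(exposure=spec.exposure, exposure_cols=spec.exposure_cols,
                      covariates=spec.covariates,
                      interactions=tuple(spec.interactions) + ((a, b),),
                      ties=spec.ties, tol=spec.tol, max_iter=spec.max_iter,
                      cluster_correction=spec.cluster_correction)
    fit_ = fit(records, spec2, weight_col=weight_col, cluster_col=cluster_col)
    stat, df, p = fit_.wald_test(f"{a}:{b}")
    return stat, df, p, fit_
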