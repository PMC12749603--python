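"""Disease-specific survival: Kaplan-Meier estimation, the log-rank test and
Cox proportional-hazards regression.

The endpoint is disease-specific death: deaths from other causes and living
patients are censored. The Cox fit maximizes the partial likelihood by
Newton's method and supports both the Efron (default) and Breslow tie
conventions; confidence intervals are Wald at 95%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "KMFit",
    "CoxFit",
    "dss_prepare",
    "km_fit",
    "log_rank",
    "cox_fit",
]


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # months since diagnosis
    event: int  # 1 = death from disease, 0 = censored

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def dss_prepare(clinical: ClinicalTable, endpoint: str = "disease") -> list[SurvivalRecord]:
    """Turn the clinical table into disease-specific survival records.

    ``endpoint='overall'`` counts any death as an event (non-default).
    """
    records = []
    for _, row in clinical.df.iterrows():
        cause = row["death_cause"]
        if endpoint == "disease":
            event = 1 if cause == "disease" else 0
        elif endpoint == "overall":
            event = 1 if cause in ("disease", "other") else 0
        else:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        records.append(SurvivalRecord(row["sample_id"], float(row["surv_time_months"]), event))
    return records


def _to_arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    ids = [r.sample_id for r in records]
    return t, e, ids


@dataclass
class KMFit:
    """Product-limit estimate: one row per distinct event time."""

    table: pd.DataFrame  # time, n_at_risk, n_events, n_censored, survival

    def survival_at(self, t: float) -> float:
        times = self.table["time"].to_numpy()
        surv = self.table["survival"].to_numpy()
        idx = np.searchsorted(times, t, side="right") - 1
        return 1.0 if idx < 0 else float(surv[idx])


def km_fit(records: list[SurvivalRecord],
           groups: dict[str, str] | None = None) -> dict[str, KMFit]:
    """Kaplan-Meier per group (single group ``'all'`` when groups is None).

    At a tied time, events are processed before censorings.
    """
    if not records:
        raise ValueError("no records")
    if groups is None:
        groups = {r.sample_id: "all" for r in records}
    by_group: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        if r.sample_id not in groups:
            raise KeyError(f"no group for sample {r.sample_id}")
        by_group.setdefault(groups[r.sample_id], []).append(r)
    out = {}
    for g, recs in by_group.items():
        if not recs:
            raise ValueError(f"empty group {g}")
        out[g] = _km_single(recs)
    return out


def _km_single(records: list[SurvivalRecord]) -> KMFit:
    t, e, _ = _to_arrays(records)
    order = np.lexsort((1 - e, t))  # time asc, events before censorings
    t, e = t[order], e[order]
    n = len(t)
    rows = []
    surv = 1.0
    i = 0
    at_risk = n
    while i < n:
        ti = t[i]
        j = i
        d = c = 0
        while j < n and t[j] == ti:
            if e[j] == 1:
                d += 1
            else:
                c += 1
            j += 1
        if d > 0:
            surv *= 1.0 - d / at_risk
            rows.append({"time": ti, "n_at_risk": at_risk, "n_events": d,
                         "n_censored": c, "survival": surv})
        at_risk -= d + c
        i = j
    table = pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                        "n_censored", "survival"])
    return KMFit(table=table)


def log_rank(records: list[SurvivalRecord], groups: dict[str, str]):
    """Unweighted k-group log-rank test, chi-square on k-1 degrees of freedom."""
    from .associations import TestResult

    t, e, ids = _to_arrays(records)
    glabels = np.array([groups[s] for s in ids])
    levels = sorted(set(glabels))
    k = len(levels)
    if k < 2:
        raise ValueError("log-rank requires at least 2 groups")
    if e.sum() == 0:
        raise ValueError("log-rank requires at least 1 event")
    gidx = np.array([levels.index(g) for g in glabels])

    event_times = np.unique(t[e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for ti in event_times:
        at_risk = t >= ti
        N = at_risk.sum()
        if N == 0:
            continue
        dying = (t == ti) & (e == 1)
        d = dying.sum()
        Nj = np.bincount(gidx[at_risk], minlength=k).astype(float)
        Oj = np.bincount(gidx[dying], minlength=k).astype(float)
        observed += Oj
        expected += d * Nj / N
        if N > 1:
            factor = d * (N - d) / (N - 1)
            p = Nj / N
            var += factor * (np.diag(p) - np.outer(p, p))
    diff = (observed - expected)[:-1]
    V = var[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(V, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(V) @ diff)
    p_value = float(stats.chi2.sf(stat, k - 1))
    return TestResult("log-rank", stat, p_value, df=float(k - 1), n_used=len(records))


@dataclass
class CoxFit:
    """Per-covariate coefficients, hazard ratios, Wald 95% CIs and p-values."""

    table: pd.DataFrame  # beta, se, hr, ci_low, ci_high, p per covariate
    n: int
    n_events: int
    ties: str
    converged: bool
    separation_flag: bool = False
    log_likelihood: float = float("nan")


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Indicator-code non-numeric columns (first level dropped as reference)."""
    numeric = covariates.select_dtypes(include=[np.number])
    categorical = covariates.select_dtypes(exclude=[np.number])
    parts = [numeric.astype(float)]
    if not categorical.empty:
        parts.append(pd.get_dummies(categorical, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def cox_fit(records: list[SurvivalRecord], covariates: pd.DataFrame,
            ties: str = "efron", max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson on the partial likelihood.

    ``covariates`` is indexed by sample_id; only complete cases (no NaN in any
    covariate) enter the model. Requires at least as many events as
    covariate columns after indicator coding.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    ids = [r.sample_id for r in records]
    missing = [s for s in ids if s not in covariates.index]
    if missing:
        raise KeyError(f"covariates missing for samples: {missing[:5]}")
    X_df = _design_matrix(covariates.loc[ids])
    complete = ~X_df.isna().any(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("cox_fit: %d incomplete cases excluded", n_dropped)
    recs = [r for r, ok in zip(records, complete) if ok]
    X = X_df.to_numpy(dtype=float)[complete]
    t, e, _ = _to_arrays(recs)
    n, p = X.shape
    if e.sum() < p:
        raise ValueError(f"{int(e.sum())} events < {p} covariates")

    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]

    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = _partial_loglik(beta, t, e, X, ties)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular information matrix (separation or collinearity)")
        # step-halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, _, _ = _partial_loglik(cand, t, e, X, ties, derivatives=False)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        if abs(ll_new - ll_prev) < tol * (abs(ll_prev) + 1):
            converged = True
            ll_prev = ll_new
            break
        ll_prev = ll_new
    if not converged:
        _, grad, _ = _partial_loglik(beta, t, e, X, ties)
        gnorm = float(np.linalg.norm(grad))
        if gnorm > 1e-4:
            raise RuntimeError(
                f"Cox fit did not converge in {max_iter} iterations "
                f"(gradient norm {gnorm:.3g})"
            )
        converged = True

    separation = bool(np.abs(beta).max() > 15)
    if separation:
        logger.warning("cox_fit: very large coefficient, possible monotone likelihood")

    _, _, hess = _partial_loglik(beta, t, e, X, ties)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - zcrit * se),
            "ci_high": np.exp(beta + zcrit * se),
            "p": pvals,
        },
        index=X_df.columns,
    )
    return CoxFit(table=table, n=n, n_events=int(e.sum()), ties=ties,
                  converged=converged, separation_flag=separation,
                  log_likelihood=float(ll_prev))


def _partial_loglik(beta, t, e, X, ties, derivatives: bool = True):
    """Partial log-likelihood with gradient and Hessian (inputs time-sorted)."""
    n, p = X.shape
    eta = X @ beta
    # guard against overflow in exp for wild Newton steps
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X

    # suffix sums over the risk set (t sorted ascending -> risk set is a suffix)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = None
    if derivatives:
        wxx = wx[:, :, None] * X[:, None, :]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        ti = t[i]
        j = i
        death_idx = []
        while j < n and t[j] == ti:
            if e[j] == 1:
                death_idx.append(j)
            j += 1
        if death_idx:
            D = np.array(death_idx)
            d = len(D)
            s0 = S0[i]
            s1 = S1[i]
            s2 = S2[i] if derivatives else None
            sum_eta = eta[D].sum()
            if ties == "breslow" or d == 1:
                ll += sum_eta - d * np.log(s0)
                if derivatives:
                    mu = s1 / s0
                    grad += X[D].sum(axis=0) - d * mu
                    hess -= d * (s2 / s0 - np.outer(mu, mu))
            else:  # efron
                wD = w[D].sum()
                s1D = wx[D].sum(axis=0)
                s2D = wxx[D].sum(axis=0) if derivatives else None
                ll += sum_eta
                xD = X[D].sum(axis=0)
                for l in range(d):
                    f = l / d
                    denom = s0 - f * wD
                    ll -= np.log(denom)
                    if derivatives:
                        mu = (s1 - f * s1D) / denom
                        grad -= mu
                        hess -= (s2 - f * s2D) / denom - np.outer(mu, mu)
                if derivatives:
                    grad += xD
        i = j
    return ll, grad, hess
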