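"""Cross-tabulations and rank-based association tests.

All tests are two-sided; missing values are excluded pairwise per test and
the exclusion count is part of every result. No multiple-testing adjustment
is applied to the association battery — raw p-values are reported, and that
choice is logged prominently at the battery level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .io import ClinicalTable

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "TestResult",
    "crosstab",
    "chi_square",
    "mann_whitney",
    "kruskal_wallis",
    "spearman",
    "logistic_predict_basal",
]

MISSING = "missing"


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    n_used: int = 0
    n_missing_excluded: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ContingencyTable:
    """Counts with within-column percentages (one decimal)."""

    counts: pd.DataFrame  # rows x columns, integer counts
    n_missing_excluded: int = 0

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def percent_within_column(self) -> pd.DataFrame:
        """Each column expressed as percentages of its total, one decimal."""
        pct = 100.0 * self.counts / self.counts.sum(axis=0)
        return pct.round(1)


def crosstab(clinical: ClinicalTable, var_row: str, var_col: str) -> ContingencyTable:
    """Cross-tabulate two categorical clinical variables.

    Rows with a missing value in either variable are excluded and counted.
    """
    df = clinical.df
    for v in (var_row, var_col):
        if v not in df.columns:
            raise KeyError(f"unknown clinical variable {v!r}")
    rows = df[var_row].astype(str)
    cols = df[var_col].astype(str)
    ok = (rows != MISSING) & (cols != MISSING)
    n_excl = int((~ok).sum())
    if ok.sum() == 0:
        raise ValueError("contingency table empty after excluding missing values")
    counts = pd.crosstab(rows[ok], cols[ok])
    counts.index.name = var_row
    counts.columns.name = var_col
    return ContingencyTable(counts=counts, n_missing_excluded=n_excl)


def chi_square(table: ContingencyTable) -> TestResult:
    """Uncorrected Pearson chi-square on an r x c table, two-sided upper tail."""
    obs = table.counts.to_numpy(dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return TestResult(
        test_name="pearson-chi-square",
        statistic=float(stat),
        p_value=float(p),
        df=float(dof),
        n_used=table.grand_total,
        n_missing_excluded=table.n_missing_excluded,
    )


def mann_whitney(x, y, exact: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U.

    Default is the tie-corrected normal approximation; exact enumeration is
    used automatically when both groups have <= 10 untied observations
    (``exact='never'``/``'always'`` to override).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    if exact == "always":
        method = "exact"
    elif exact == "never":
        method = "asymptotic"
    else:
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 10 and len(y) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann-whitney-u", float(res.statistic), float(res.pvalue),
                      n_used=len(x) + len(y))


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H, chi-square p on k-1 df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    res = stats.kruskal(*arrays)
    return TestResult("kruskal-wallis-h", float(res.statistic), float(res.pvalue),
                      df=float(len(arrays) - 1), n_used=sum(len(a) for a in arrays))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), p by t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("spearman needs >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class LogisticFit:
    coefficients: pd.DataFrame  # beta, odds_ratio, p per feature (+const)
    converged: bool
    separation_flag: bool
    n: int


def logistic_predict_basal(features: pd.DataFrame, labels) -> LogisticFit:
    """Multivariate logistic regression of a binary label on score + covariates.

    Maximum likelihood via iteratively reweighted least squares; Wald p per
    coefficient. Perfect separation is flagged (coefficients still reported
    with a warning); perfectly collinear feature columns are an error.
    """
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    X = features.astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("perfectly collinear feature columns")
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, method="newton", maxiter=100)
        converged = bool(fit.mle_retvals.get("converged", True))
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        separation = True
        fit = sm.Logit(y, Xc).fit_regularized(disp=0, alpha=1e-8, maxiter=200)
        converged = False
    params = fit.params
    try:
        pvals = fit.pvalues
    except Exception:  # regularized fits lack covariance
        pvals = pd.Series(np.nan, index=params.index)
    if not separation and np.abs(params).max() > 15:
        separation = True
    if separation:
        logger.warning("logistic fit: possible perfect separation; interpret with care")
    coefs = pd.DataFrame(
        {"beta": params, "odds_ratio": np.exp(params), "p": pvals}
    )
    return LogisticFit(coefficients=coefs, converged=converged,
                       separation_flag=separation, n=len(y))


def association_report(clinical: ClinicalTable, pairs) -> pd.DataFrame:
    """Chi-square battery over variable pairs; raw p-values, no adjustment."""
    logger.warning(
        "association battery reports RAW p-values; no multiple-testing adjustment"
    )
    rows = []
    for var_row, var_col in pairs:
        ct = crosstab(clinical, var_row, var_col)
        res = chi_square(ct)
        rows.append(
            {
                "var_row": var_row,
                "var_col": var_col,
                "test": res.test_name,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "n_used": res.n_used,
                "n_missing": res.n_missing_excluded,
            }
        )
    return pd.DataFrame(rows)
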