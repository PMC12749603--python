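"""Two-class permutation differential expression with a moderated t-statistic,
signed fold changes, and threshold-based derivation of a directional signature.

Per gene the statistic is d = (mean_g1 - mean_g2) / (s + s0), where s is the
pooled standard error of the mean difference and s0 a small stabilizing
constant ("fudge factor"). The false discovery rate attached to each gene is
estimated from group-label permutations: for gene i,

    q_i = 100 * median_b #{j : |d*_bj| >= |d_i|} / #{j : |d_j| >= |d_i|}

capped at 100 and made monotone non-increasing in |d|. Group 1 is the
condition-positive group, so positive fold change means higher expression in
the positive group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .signatures import SignatureDefinition

if TYPE_CHECKING:  # pragma: no cover
    from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEConfig",
    "DEResult",
    "GroupLabels",
    "sam_statistic",
    "estimate_s0",
    "signed_fold_change",
    "permutation_q",
    "run_diffexp",
    "derive_signature",
]


@dataclass(frozen=True)
class DEConfig:
    """Parameters of the permutation differential-expression run.

    ``q_max_percent`` is on the percent scale: the default 0.008 means an
    estimated FDR below 0.008% (8e-5 as a proportion).
    """

    n_permutations: int = 1000
    seed: int | None = None
    s0_mode: str = "median"  # median | fixed | percentile-search
    s0_value: float | None = None  # used with s0_mode == "fixed"
    fc_min: float = 2.5
    q_max_percent: float = 0.008

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1 (linear-scale fold change)")
        if not 0 <= self.q_max_percent <= 100:
            raise ValueError("q_max_percent must be in [0, 100]")
        if self.s0_mode not in ("median", "fixed", "percentile-search"):
            raise ValueError(f"unknown s0_mode {self.s0_mode!r}")
        if self.s0_mode == "fixed" and (self.s0_value is None or self.s0_value < 0):
            raise ValueError("s0_mode='fixed' requires a non-negative s0_value")
        if self.seed is None:
            raise ValueError("seed is mandatory for permutation reproducibility")


@dataclass
class GroupLabels:
    """sample_id -> group assignment; group1 is the condition-positive group."""

    group1: list[str]
    group2: list[str]

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("both groups must be non-empty")
        overlap = set(self.group1) & set(self.group2)
        if overlap:
            raise ValueError(f"samples in both groups: {sorted(overlap)[:5]}")

    @property
    def all_samples(self) -> list[str]:
        return list(self.group1) + list(self.group2)

    def validate_against(self, matrix: "ExpressionMatrix") -> None:
        if set(self.all_samples) != set(matrix.sample_ids):
            raise ValueError("group labels must cover exactly the matrix's samples")

    @classmethod
    def from_clinical(cls, clinical, field: str = "necrosis",
                      positive: str = "present", negative: str = "absent") -> "GroupLabels":
        col = clinical.column(field)
        g1 = col.index[col == positive].tolist()
        g2 = col.index[col == negative].tolist()
        return cls(group1=g1, group2=g2)


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    Columns of ``table``: mean_g1, mean_g2 (log2 units), fc_signed (linear
    scale, |fc| >= 1), d, s, q_percent, direction.
    """

    table: pd.DataFrame
    s0: float
    config: DEConfig
    n_group1: int = 0
    n_group2: int = 0
    exhaustive: bool = False

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def _split_values(matrix: "ExpressionMatrix", labels: GroupLabels) -> tuple[np.ndarray, np.ndarray]:
    labels.validate_against(matrix)
    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    c1 = [idx[s] for s in labels.group1]
    c2 = [idx[s] for s in labels.group2]
    return matrix.values[:, c1], matrix.values[:, c2]


def _pooled_se(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Pooled standard error of the difference in means (per row)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = (ss1 + ss2) / (n1 + n2 - 2)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * pooled_var)


def _d_statistic(x1: np.ndarray, x2: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    num = x1.mean(axis=1) - x2.mean(axis=1)
    s = _pooled_se(x1, x2)
    denom = s + s0
    if (denom == 0).any():
        raise ValueError(
            "zero-variance gene with s0 = 0 gives an infinite statistic; use s0 > 0"
        )
    return num / denom, s


def sam_statistic(
    matrix: "ExpressionMatrix", labels: GroupLabels, s0: float = 0.0
) -> pd.DataFrame:
    """Per-gene moderated statistic d and pooled standard error s.

    With ``s0 = 0`` d is exactly the classical pooled-variance two-sample
    t-statistic. Each group needs at least 2 samples.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    x1, x2 = _split_values(matrix, labels)
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    d, s = _d_statistic(x1, x2, s0)
    return pd.DataFrame({"d": d, "s": s}, index=matrix.gene_ids)


def estimate_s0(s_values: np.ndarray, mode: str = "median",
                fixed_value: float | None = None,
                d_numerators: np.ndarray | None = None) -> float:
    """Choose the stabilizing constant s0 from the per-gene standard errors.

    ``median``: the median of s. ``fixed``: the supplied value.
    ``percentile-search``: the s-percentile in {0, 5, ..., 95} that minimizes
    the coefficient of variation of the d spread across s-windows; requires
    the per-gene numerators (mean differences).
    """
    s = np.asarray(s_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty s_values")
    if (s < 0).any():
        raise ValueError("s_values must be non-negative")
    if mode == "median":
        return float(np.median(s))
    if mode == "fixed":
        if fixed_value is None or fixed_value < 0:
            raise ValueError("fixed mode requires a non-negative value")
        return float(fixed_value)
    if mode == "percentile-search":
        if d_numerators is None:
            raise ValueError("percentile-search requires the per-gene numerators")
        return _percentile_search_s0(s, np.asarray(d_numerators, dtype=float))
    raise ValueError(f"unknown s0 mode {mode!r}")


def _percentile_search_s0(s: np.ndarray, num: np.ndarray) -> float:
    """Percentile search for s0: minimize the coefficient of variation of the
    windowed spread of d over candidate percentiles of s."""
    percentiles = np.arange(0, 100, 5)
    candidates = np.percentile(s, percentiles)
    # windows: deciles of s (degenerate s collapses to one window)
    edges = np.unique(np.percentile(s, np.linspace(0, 100, 11)))
    window_of = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, len(edges) - 2) \
        if len(edges) > 1 else np.zeros(len(s), dtype=int)
    best_cv, best_s0 = math.inf, float(candidates[0])
    for cand in candidates:
        d = num / (s + cand) if cand > 0 else _safe_ratio(num, s)
        spreads = []
        for w in range(max(1, len(edges) - 1)):
            dw = d[window_of == w]
            if dw.size:
                spreads.append(_mad(dw))
        spreads = np.asarray(spreads)
        if spreads.size == 0 or spreads.mean() == 0:
            cv = 0.0
        else:
            cv = spreads.std(ddof=0) / spreads.mean()
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))) / 0.64)


def signed_fold_change(matrix: "ExpressionMatrix", labels: GroupLabels) -> pd.Series:
    """Linear-scale signed fold change from log2 group means.

    r = 2^(mean_g1 - mean_g2); reported as r when r >= 1, else -1/r, so the
    magnitude is always >= 1 and the sign follows the mean difference.
    """
    x1, x2 = _split_values(matrix, labels)
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    r = np.power(2.0, diff)
    fc = np.where(r >= 1, r, -1.0 / r)
    return pd.Series(fc, index=matrix.gene_ids, name="fc_signed")


def _distinct_permutation_count(n1: int, n2: int) -> int:
    return math.comb(n1 + n2, n1)


def _permutation_splits(n1: int, n2: int, B: int, rng: np.random.Generator
                        ) -> tuple[np.ndarray, bool]:
    """Column-index matrix of group-1 assignments for each permutation.

    Falls back to exhaustive enumeration of all distinct splits when B exceeds
    the number available (tiny fixtures); the flag reports which route ran.
    """
    n = n1 + n2
    total = _distinct_permutation_count(n1, n2)
    if B >= total:
        logger.warning(
            "permutation_q: B=%d >= %d distinct splits; using exhaustive enumeration",
            B, total,
        )
        splits = np.array(list(combinations(range(n), n1)), dtype=int)
        return splits, True
    picks = np.empty((B, n1), dtype=int)
    for b in range(B):
        picks[b] = rng.permutation(n)[:n1]
    return picks, False


def permutation_q(
    matrix: "ExpressionMatrix", labels: GroupLabels, config: DEConfig,
    s0: float | None = None,
) -> pd.Series:
    """Permutation FDR per gene, in percent.

    Uses the observed-data s0 for every permutation; q is capped at 100 and
    monotonized so genes with larger |d| never get a larger q.
    """
    res = run_diffexp(matrix, labels, config, s0=s0)
    return res.table["q_percent"]


def run_diffexp(
    matrix: "ExpressionMatrix", labels: GroupLabels, config: DEConfig,
    s0: float | None = None,
) -> DEResult:
    """Full two-class run: statistics, fold changes and permutation q-values."""
    x1, x2 = _split_values(matrix, labels)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    num = x1.mean(axis=1) - x2.mean(axis=1)
    s = _pooled_se(x1, x2)
    if s0 is None:
        s0 = estimate_s0(s, mode=config.s0_mode, fixed_value=config.s0_value,
                         d_numerators=num)
    d, _ = _d_statistic(x1, x2, s0)

    rng = np.random.default_rng(config.seed)
    all_vals = np.hstack([x1, x2])
    splits, exhaustive = _permutation_splits(n1, n2, config.n_permutations, rng)

    abs_d = np.abs(d)
    order = np.argsort(abs_d)  # ascending
    sorted_abs = abs_d[order]
    n_genes = len(abs_d)
    # observed counts: #{j: |d_j| >= |d_i|}
    obs_ge = n_genes - np.searchsorted(sorted_abs, abs_d, side="left")

    perm_counts = np.empty((len(splits), n_genes), dtype=np.int64)
    for b, pick in enumerate(splits):
        mask = np.zeros(all_vals.shape[1], dtype=bool)
        mask[pick] = True
        p1 = all_vals[:, mask]
        p2 = all_vals[:, ~mask]
        dstar, _ = _d_statistic(p1, p2, s0)
        sorted_star = np.sort(np.abs(dstar))
        perm_counts[b] = n_genes - np.searchsorted(sorted_star, abs_d, side="left")
    med_false = np.median(perm_counts, axis=0)
    q = 100.0 * med_false / obs_ge
    q = np.minimum(q, 100.0)
    # monotonize: walking down from the largest |d|, q may only grow
    desc = order[::-1]
    q_desc = np.maximum.accumulate(q[desc])
    q_mono = np.empty_like(q)
    q_mono[desc] = q_desc

    r = np.power(2.0, num)
    fc = np.where(r >= 1, r, -1.0 / r)
    direction = np.where(
        (fc >= config.fc_min) & (q_mono < config.q_max_percent), "UP",
        np.where((fc <= -config.fc_min) & (q_mono < config.q_max_percent), "DOWN", "none"),
    )
    table = pd.DataFrame(
        {
            "mean_g1": x1.mean(axis=1),
            "mean_g2": x2.mean(axis=1),
            "fc_signed": fc,
            "d": d,
            "s": s,
            "q_percent": q_mono,
            "direction": direction,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    return DEResult(table=table, s0=float(s0), config=config,
                    n_group1=n1, n_group2=n2, exhaustive=exhaustive)


def derive_signature(de: DEResult, config: DEConfig | None = None,
                     name: str = "signature") -> SignatureDefinition:
    """Threshold the run into a directional signature.

    UP: fc_signed >= fc_min and q below the (percent-scale) cut-off;
    DOWN: fc_signed <= -fc_min under the same q cut-off.
    """
    cfg = config or de.config
    t = de.table
    pass_q = t["q_percent"] < cfg.q_max_percent
    up = set(t.index[(t["fc_signed"] >= cfg.fc_min) & pass_q])
    down = set(t.index[(t["fc_signed"] <= -cfg.fc_min) & pass_q])
    if not up and not down:
        raise ValueError(
            f"no genes pass thresholds (fc >= |{cfg.fc_min}|, q < {cfg.q_max_percent}%)"
        )
    logger.info("derive_signature(%s): %d UP, %d DOWN genes", name, len(up), len(down))
    return SignatureDefinition(name=name, up_genes=frozenset(up), down_genes=frozenset(down))


def write_de_table(de: DEResult, path) -> None:
    de.table.to_csv(path, sep="\t", float_format="%.6g")
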