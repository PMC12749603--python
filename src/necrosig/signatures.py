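"""Directional sum-scores, score grouping schemes, panel normalization,
signature overlap and hierarchical clustering of score tables.

The primary score of the pipeline is the directional sum: per sample, the sum
of log2 expression over the signature's UP genes minus the sum over its DOWN
genes. Grouping schemes (zero cut-off, mean split, quartiles) turn the score
into categorical labels consumed by the association and survival stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

if TYPE_CHECKING:  # pragma: no cover
    from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureDefinition",
    "ScoreVector",
    "score_signature",
    "dichotomize_zero",
    "split_mean",
    "split_quartiles",
    "score_panel",
    "jaccard",
    "hcluster",
]


@dataclass(frozen=True)
class SignatureDefinition:
    """A named directional gene set: UP genes add to the score, DOWN genes subtract."""

    name: str
    up_genes: frozenset[str] = field(default_factory=frozenset)
    down_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "down_genes", frozenset(self.down_genes))
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: genes in both directions: {sorted(overlap)[:5]}"
            )
        if not (self.up_genes or self.down_genes):
            raise ValueError(f"signature {self.name!r} is empty")

    @property
    def genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ScoreVector:
    """Per-sample signature scores with the number of signature genes that
    were absent from the matrix (skipped, never imputed)."""

    signature_name: str
    scores: pd.Series  # index sample_id
    n_missing_up: int = 0
    n_missing_down: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def score_signature(
    matrix: "ExpressionMatrix", sig: SignatureDefinition
) -> ScoreVector:
    """Sum of UP-gene expression minus sum of DOWN-gene expression per sample.

    Signature genes absent from the matrix are skipped and counted in the
    result; a signature with no gene present at all is an error.
    """
    gene_idx = matrix.gene_index()
    up_rows = [gene_idx[g] for g in sorted(sig.up_genes) if g in gene_idx]
    down_rows = [gene_idx[g] for g in sorted(sig.down_genes) if g in gene_idx]
    n_missing_up = len(sig.up_genes) - len(up_rows)
    n_missing_down = len(sig.down_genes) - len(down_rows)
    if not up_rows and not down_rows:
        raise ValueError(
            f"no genes of signature {sig.name!r} found in the expression matrix"
        )
    if n_missing_up or n_missing_down:
        logger.warning(
            "score_signature(%s): %d UP and %d DOWN genes missing from matrix",
            sig.name,
            n_missing_up,
            n_missing_down,
        )
    scores = np.zeros(matrix.n_samples)
    if up_rows:
        scores += matrix.values[up_rows].sum(axis=0)
    if down_rows:
        scores -= matrix.values[down_rows].sum(axis=0)
    return ScoreVector(
        signature_name=sig.name,
        scores=pd.Series(scores, index=matrix.sample_ids, name=sig.name),
        n_missing_up=n_missing_up,
        n_missing_down=n_missing_down,
    )


def dichotomize_zero(scores: pd.Series) -> pd.Series:
    """'high' for strictly positive scores, 'low' otherwise (zero -> low)."""
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("scores must be finite")
    return pd.Series(
        np.where(scores.to_numpy() > 0, "high", "low"), index=scores.index, name="group"
    )


def split_mean(scores: pd.Series) -> pd.Series:
    """'above' for scores strictly greater than the arithmetic mean, else 'below'."""
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    return pd.Series(
        np.where(vals > vals.mean(), "above", "below"), index=scores.index, name="group"
    )


def split_quartiles(scores: pd.Series) -> pd.Series:
    """Rank-based quartiles Q1..Q4, Q4 = highest scores.

    Boundaries come from sample ranks; tied scores are kept together in the
    lower quartile, so group sizes may be unequal (logged).
    """
    vals = scores.to_numpy(dtype=float)
    if len(vals) < 4:
        raise ValueError("quartile split requires at least 4 samples")
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    n = len(vals)
    # min rank among ties -> a whole tie block lands in the lower quartile
    ranks = pd.Series(vals).rank(method="min").to_numpy()
    labels = np.empty(n, dtype=object)
    for i, r in enumerate(ranks):
        frac = r / n
        if frac <= 0.25:
            labels[i] = "Q1"
        elif frac <= 0.50:
            labels[i] = "Q2"
        elif frac <= 0.75:
            labels[i] = "Q3"
        else:
            labels[i] = "Q4"
    out = pd.Series(labels, index=scores.index, name="group")
    sizes = out.value_counts()
    if sizes.nunique() > 1:
        logger.warning("split_quartiles: unequal group sizes %s", sizes.to_dict())
    if len(sizes) == 1:
        logger.warning("split_quartiles: all scores tied, single quartile group")
    return out


def score_panel(
    matrix: "ExpressionMatrix", signatures: Sequence[SignatureDefinition]
) -> pd.DataFrame:
    """Score every signature and z-normalize each column (mean 0, sd 1).

    Zero-variance columns are left at 0 with a warning. The sd is the sample
    standard deviation (ddof=1).
    """
    cols = {}
    for sig in signatures:
        sv = score_signature(matrix, sig)
        raw = sv.scores.to_numpy(dtype=float)
        sd = raw.std(ddof=1) if len(raw) > 1 else 0.0
        if sd == 0:
            logger.warning("score_panel: signature %s has zero variance", sig.name)
            z = np.zeros_like(raw)
        else:
            z = (raw - raw.mean()) / sd
        cols[sig.name] = z
    return pd.DataFrame(cols, index=matrix.sample_ids)


def jaccard(a: SignatureDefinition, b: SignatureDefinition) -> float:
    """Jaccard index between the full gene memberships (UP union DOWN)."""
    ga, gb = a.genes, b.genes
    union = ga | gb
    if not union:
        raise ValueError("both signatures empty")
    return len(ga & gb) / len(union)


@dataclass
class ClusterResult:
    labels: list[str]
    merge_tree: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]


def hcluster(score_table: pd.DataFrame, axis: str = "columns") -> ClusterResult:
    """Agglomerative clustering with complete linkage and Euclidean distance.

    Clusters the table's columns by default (``axis='rows'`` for samples);
    returns the merge tree and the deterministic leaf ordering, no rendering.
    """
    if axis not in ("columns", "rows"):
        raise ValueError("axis must be 'columns' or 'rows'")
    data = score_table.to_numpy(dtype=float)
    labels = list(score_table.columns) if axis == "columns" else list(score_table.index)
    if axis == "columns":
        data = data.T
    if data.shape[0] < 2:
        raise ValueError("clustering needs at least 2 items")
    if not np.isfinite(data).all():
        raise ValueError("non-finite values in score table")
    tree = linkage(data, method="complete", metric="euclidean")
    order = [labels[i] for i in leaves_list(tree)]
    return ClusterResult(labels=labels, merge_tree=tree, leaf_order=order)
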