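"""Group-wise somatic mutation comparison: per-sample burden, per-gene
mutated-sample frequencies, per-gene Fisher tests with Benjamini-Hochberg
adjustment, and pathway-level aggregation.

The default variant filter keeps every variant class; a nonsynonymous-only
preset is available since frequency panels conventionally use it. Both
choices are logged by the callers that apply them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MutationTable

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayMap",
    "mutation_burden",
    "gene_freq_by_group",
    "per_gene_test",
    "pathway_burden",
    "bh_adjust",
]


@dataclass
class PathwayMap:
    """pathway name -> set of member genes (each pathway non-empty)."""

    pathways: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")

    @classmethod
    def from_signatures(cls, signatures) -> "PathwayMap":
        return cls({sig.name: set(sig.genes) for sig in signatures})


def _check_groups(mt: MutationTable, groups: dict[str, str]) -> None:
    uncovered = set(mt.sample_universe) - set(groups)
    if uncovered:
        raise ValueError(f"samples without group label: {sorted(uncovered)[:5]}")


def mutation_burden(mt: MutationTable, groups: dict[str, str],
                    dedup: bool = False) -> tuple[pd.Series, pd.Series]:
    """Per-sample mutation counts and per-group means.

    Counts all records per sample (all variant classes); mutation-free
    samples count 0. With ``dedup=True`` identical (sample, gene, class)
    records are counted once — logged either way.
    """
    _check_groups(mt, groups)
    recs = mt.records
    if dedup:
        before = len(recs)
        recs = recs.drop_duplicates()
        logger.info("mutation_burden: dedup removed %d duplicate records", before - len(recs))
    else:
        logger.info("mutation_burden: counting all %d records (no dedup)", len(recs))
    counts = recs.groupby("sample_id").size()
    per_sample = pd.Series(0, index=pd.Index(mt.sample_universe, name="sample_id"),
                           dtype=int)
    per_sample.loc[counts.index] = counts
    glabels = pd.Series({s: groups[s] for s in mt.sample_universe}, name="group")
    group_means = per_sample.groupby(glabels).mean()
    return per_sample, group_means


def _mutated_indicator(mt: MutationTable) -> pd.DataFrame:
    """Samples x genes boolean table: True if the sample has >= 1 record in the gene."""
    flags = (
        mt.records.assign(flag=True)
        .pivot_table(index="sample_id", columns="gene", values="flag",
                     aggfunc="any", fill_value=False)
    )
    return flags.reindex(mt.sample_universe, fill_value=False).astype(bool)


def gene_freq_by_group(mt: MutationTable, groups: dict[str, str],
                       top_k: int | None = None) -> pd.DataFrame:
    """Per-gene mutated-sample fraction within each group.

    Genes are ranked by overall frequency (descending, ties by name for
    determinism); ``top_k`` keeps the most frequent genes only. Returns a
    table with one row per gene: per-group fractions plus overall.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    _check_groups(mt, groups)
    ind = _mutated_indicator(mt)
    glabels = pd.Series({s: groups[s] for s in mt.sample_universe})
    overall = ind.mean(axis=0)
    per_group = ind.groupby(glabels).mean().T  # genes x groups
    out = per_group.copy()
    out["overall"] = overall
    # rank by overall frequency, ties broken by gene name for determinism
    order = np.lexsort((out.index.to_numpy(), -out["overall"].to_numpy()))
    out = out.iloc[order]
    if top_k is not None:
        out = out.head(top_k)
    return out


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p (hypergeometric point-probability method)."""
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def per_gene_test(mt: MutationTable, groups: dict[str, str],
                  min_mutated: int = 1) -> pd.DataFrame:
    """Per-gene 2x2 Fisher exact test (mutated/not x group) with BH adjustment.

    Genes mutated in fewer than ``min_mutated`` samples overall are skipped
    with a log entry. Exactly two groups required.
    """
    _check_groups(mt, groups)
    levels = sorted(set(groups[s] for s in mt.sample_universe))
    if len(levels) != 2:
        raise ValueError(f"per-gene test requires exactly 2 groups, got {levels}")
    ind = _mutated_indicator(mt)
    glabels = pd.Series({s: groups[s] for s in mt.sample_universe})
    in_g1 = (glabels == levels[0]).reindex(ind.index).to_numpy()
    n1, n2 = int(in_g1.sum()), int((~in_g1).sum())
    rows = []
    for gene in ind.columns:
        mut = ind[gene].to_numpy()
        a = int((mut & in_g1).sum())
        b = int((mut & ~in_g1).sum())
        if a + b < min_mutated:
            logger.info("per_gene_test: gene %s skipped (no mutated samples)", gene)
            continue
        table = np.array([[a, b], [n1 - a, n2 - b]])
        p = fisher_exact_2x2(table)
        rows.append({"gene": gene, f"frac_{levels[0]}": a / n1,
                     f"frac_{levels[1]}": b / n2,
                     f"n_mut_{levels[0]}": a, f"n_mut_{levels[1]}": b, "p": p})
    if not rows:
        return pd.DataFrame(columns=["gene", "p", "q"]).set_index("gene")
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.iloc[np.lexsort((out.index.to_numpy(), out["p"].to_numpy()))]


def pathway_burden(mt: MutationTable, pmap: PathwayMap,
                   groups: dict[str, str]) -> pd.DataFrame:
    """Per-pathway fraction of samples with >= 1 mutated member gene, per
    group, plus a two-sided Fisher exact test (two groups)."""
    _check_groups(mt, groups)
    levels = sorted(set(groups[s] for s in mt.sample_universe))
    if len(levels) != 2:
        raise ValueError(f"pathway test requires exactly 2 groups, got {levels}")
    ind = _mutated_indicator(mt)
    glabels = pd.Series({s: groups[s] for s in mt.sample_universe})
    in_g1 = (glabels == levels[0]).reindex(ind.index).to_numpy()
    n1, n2 = int(in_g1.sum()), int((~in_g1).sum())
    data_genes = set(ind.columns)
    rows = []
    for name, genes in pmap.pathways.items():
        members = sorted(genes & data_genes)
        if not members:
            logger.warning("pathway_burden: pathway %s has no genes in the data; skipped", name)
            continue
        hit = ind[members].any(axis=1).to_numpy()
        a = int((hit & in_g1).sum())
        b = int((hit & ~in_g1).sum())
        p = fisher_exact_2x2(np.array([[a, b], [n1 - a, n2 - b]]))
        rows.append({"pathway": name, f"frac_{levels[0]}": a / n1,
                     f"frac_{levels[1]}": b / n2, "n_genes_in_data": len(members),
                     "p": p})
    return pd.DataFrame(rows).set_index("pathway") if rows else pd.DataFrame(
        columns=["pathway", "p"]).set_index("pathway")
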