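"""Readers, writers and preprocessing for the pipeline's file formats.

Formats handled here are deliberately plain text: expression matrices as
tab-separated tables (genes x samples), clinical annotation as CSV with a
controlled vocabulary, gene sets as GMT with a ``_UP``/``_DN`` pairing
convention, and somatic mutations as MAF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "ProbeMap",
    "MutationTable",
    "FormatError",
    "read_expression",
    "write_expression",
    "log2_transform",
    "collapse_max_probe",
    "filter_cohort",
    "FilterRule",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_maf",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# controlled vocabularies for the clinical table
NECROSIS_LEVELS = ("present", "absent", "missing")
RECEPTOR_LEVELS = ("positive", "negative", "missing")
PAM50_LEVELS = ("LumA", "LumB", "Her2", "Basal", "Normal", "missing")
DEATH_CAUSE_LEVELS = ("disease", "other", "alive")
SEX_LEVELS = ("female", "male", "missing")
GRADE_LEVELS = ("1", "2", "3", "missing")
NODE_LEVELS = ("positive", "negative", "missing")

CLINICAL_COLUMNS = (
    "sample_id",
    "necrosis",
    "er",
    "pr",
    "her2",
    "pam50",
    "tumor_size_mm",
    "grade",
    "lymph_node",
    "surv_time_months",
    "death_cause",
    "sex",
)


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    Invariants (checked at construction): unique gene and sample ids, all
    values finite, dimensions consistent.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ValueError(f"duplicate gene ids: {sorted(dup_g)[:5]}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {sorted(dup_s)[:5]}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression table (first column ids, header = samples).

    Non-numeric cells raise :class:`FormatError` naming the offending
    row/column; duplicate ids violate the matrix invariants and raise too.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    fields = header.split("\t")
    if len(fields) < 2:
        raise FormatError(f"{path}: malformed header, expected id column plus >=1 sample")
    sample_ids = fields[1:]
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise FormatError(
                f"{path}: non-numeric value {df[col].loc[row]!r} at gene {row!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    try:
        return ExpressionMatrix(list(df.index), sample_ids, values)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.to_csv(path, sep="\t", float_format="%.10g")


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """Replace every value v by log2(v + pseudocount).

    Raises a domain error listing offending genes if any v + pseudocount <= 0.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    shifted = matrix.values + pseudocount
    if (shifted <= 0).any():
        bad_rows = np.flatnonzero((shifted <= 0).any(axis=1))
        genes = [matrix.gene_ids[i] for i in bad_rows[:10]]
        raise ValueError(
            f"log2 transform undefined (value + pseudocount <= 0) for genes: {genes}"
        )
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), np.log2(shifted))


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene mapping."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not isinstance(self.mapping, dict):
            self.mapping = dict(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def gene_for(self, probe: str) -> str:
        return self.mapping[probe]


def collapse_max_probe(matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    For each gene the retained row is the probe whose mean expression across
    samples is highest; ties are broken by input order (first probe wins).
    """
    if len(probe_map) == 0:
        raise ValueError("empty probe map")
    unmapped = [p for p in matrix.gene_ids if p not in probe_map.mapping]
    if unmapped:
        raise ValueError(f"probes missing from map: {unmapped[:5]}")
    means = matrix.values.mean(axis=1)
    best: dict[str, int] = {}
    gene_order: list[str] = []
    for i, probe in enumerate(matrix.gene_ids):
        gene = probe_map.gene_for(probe)
        if gene not in best:
            best[gene] = i
            gene_order.append(gene)
        elif means[i] > means[best[gene]]:  # strict: ties keep earlier probe
            best[gene] = i
    rows = [best[g] for g in gene_order]
    return ExpressionMatrix(gene_order, list(matrix.sample_ids), matrix.values[rows])


@dataclass
class ClinicalTable:
    """Per-sample phenotype table with a controlled vocabulary.

    Missing categorical values are stored as the explicit string ``missing``;
    numeric missing values as NaN. Statistical stages exclude missing values
    pairwise per test.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"clinical table missing columns: {missing_cols}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in clinical table: {dups[:5]}")
        for col, levels in (
            ("necrosis", NECROSIS_LEVELS),
            ("er", RECEPTOR_LEVELS),
            ("pr", RECEPTOR_LEVELS),
            ("her2", RECEPTOR_LEVELS),
            ("pam50", PAM50_LEVELS),
            ("death_cause", DEATH_CAUSE_LEVELS),
            ("sex", SEX_LEVELS),
            ("grade", GRADE_LEVELS),
            ("lymph_node", NODE_LEVELS),
        ):
            df[col] = df[col].fillna("missing").astype(str)
            bad = set(df[col]) - set(levels)
            if bad:
                raise FormatError(f"column {col!r}: values {sorted(bad)} not in {levels}")
        df["tumor_size_mm"] = pd.to_numeric(df["tumor_size_mm"], errors="raise")
        if (df["tumor_size_mm"].dropna() <= 0).any():
            raise ValueError("tumor_size_mm must be positive or missing")
        df["surv_time_months"] = pd.to_numeric(df["surv_time_months"], errors="raise")
        if (df["surv_time_months"] < 0).any():
            raise ValueError("surv_time_months must be >= 0")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def column(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise KeyError(name)
        return self.df.set_index("sample_id")[name]


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


@dataclass(frozen=True)
class FilterRule:
    """A single exclusion rule: drop rows whose ``field`` takes a value in ``exclude``."""

    name: str
    field: str
    exclude: tuple[str, ...]


DEFAULT_FILTER_RULES = (
    FilterRule("female-only", "sex", ("male",)),
    FilterRule("exclude-normal-like", "pam50", ("Normal",)),
)


def filter_cohort(
    clinical: ClinicalTable, rules: Sequence[FilterRule]
) -> tuple[ClinicalTable, dict[str, int]]:
    """Apply exclusion rules in order; a row removed by an earlier rule is not
    re-counted by later ones. Returns the filtered table and a per-rule log.
    """
    df = clinical.df
    for rule in rules:
        if rule.field not in df.columns:
            raise KeyError(f"filter rule {rule.name!r} references unknown field {rule.field!r}")
    keep = np.ones(len(df), dtype=bool)
    log: dict[str, int] = {}
    for rule in rules:
        hit = df[rule.field].astype(str).isin(rule.exclude).to_numpy() & keep
        log[rule.name] = int(hit.sum())
        keep &= ~hit
    filtered = ClinicalTable(df.loc[keep].reset_index(drop=True))
    for name, n in log.items():
        if n:
            logger.warning("filter_cohort: rule %s removed %d samples", name, n)
    return filtered, log


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

from .signatures import SignatureDefinition  # noqa: E402  (cycle-free: signatures has no io import)


def read_gmt(path: str | Path) -> list[SignatureDefinition]:
    """Parse a GMT file, pairing ``NAME_UP`` / ``NAME_DN`` lines into one
    directional signature. Lines without a suffix become UP-only signatures;
    an unpaired suffixed line is kept one-sided with a warning.
    """
    up_sets: dict[str, list[str]] = {}
    dn_sets: dict[str, list[str]] = {}
    suffixed: set[str] = set()
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name.upper().endswith("_UP"):
                base, target = name[: -len("_UP")], up_sets
                suffixed.add(base)
            elif name.upper().endswith("_DOWN"):
                base, target = name[: -len("_DOWN")], dn_sets
                suffixed.add(base)
            elif name.upper().endswith("_DN"):
                base, target = name[: -len("_DN")], dn_sets
                suffixed.add(base)
            else:
                base, target = name, up_sets
            if base not in up_sets and base not in dn_sets:
                order.append(base)
            target.setdefault(base, []).extend(genes)
    out = []
    for base in order:
        up = set(up_sets.get(base, []))
        down = set(dn_sets.get(base, []))
        if base in suffixed and (not up or not down):
            logger.warning(
                "read_gmt: signature %s has no %s partner; kept one-sided",
                base,
                "_DN" if not down else "_UP",
            )
        out.append(SignatureDefinition(name=base, up_genes=up, down_genes=down))
    return out


def write_gmt(signatures: Sequence[SignatureDefinition], path: str | Path) -> None:
    """Write signatures as paired ``NAME_UP`` / ``NAME_DN`` GMT lines."""
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.up_genes:
                genes = "\t".join(sorted(sig.up_genes))
                fh.write(f"{sig.name}_UP\tna\t{genes}\n")
            if sig.down_genes:
                genes = "\t".join(sorted(sig.down_genes))
                fh.write(f"{sig.name}_DN\tna\t{genes}\n")


# ---------------------------------------------------------------------------
# mutations (MAF)
# ---------------------------------------------------------------------------

MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

# conventional non-coding / silent classes, flaggable but retained on read
SILENT_CLASSES = frozenset(
    {
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "lincRNA",
    }
)


@dataclass
class MutationTable:
    """Somatic mutation records plus the full sample universe.

    The universe must contain every sample appearing in the records so that
    mutation-free samples contribute zero counts rather than vanishing.
    """

    records: pd.DataFrame  # columns sample_id, gene, variant_classification
    sample_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        needed = {"sample_id", "gene", "variant_classification"}
        if not needed.issubset(self.records.columns):
            raise ValueError(f"records need columns {sorted(needed)}")
        self.records = self.records.reset_index(drop=True)
        if not self.sample_universe:
            self.sample_universe = sorted(self.records["sample_id"].unique())
        universe = set(self.sample_universe)
        extra = set(self.records["sample_id"]) - universe
        if extra:
            raise ValueError(f"records reference samples outside the universe: {sorted(extra)[:5]}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def nonsilent(self) -> "MutationTable":
        keep = ~self.records["variant_classification"].isin(SILENT_CLASSES)
        return MutationTable(self.records.loc[keep], list(self.sample_universe))


def read_maf(path: str | Path, sample_universe: Sequence[str] | None = None) -> MutationTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: MAF missing required columns {missing}")
    records = df.rename(
        columns={
            "Hugo_Symbol": "gene",
            "Tumor_Sample_Barcode": "sample_id",
            "Variant_Classification": "variant_classification",
        }
    )[["sample_id", "gene", "variant_classification"]]
    universe = list(sample_universe) if sample_universe is not None else []
    return MutationTable(records, universe)
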