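"""Core in-memory containers: expression matrices, per-gene evolutionary tables,
sample metadata and the long-format index table.

The containers are thin, validated wrappers around :class:`pandas.DataFrame`;
all file I/O lives in :mod:`evoindex.io_qc`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The eight nested ancestral lineages on the path to human, ordered from the
#: terminal human branch outward to the haplorrhine stem.
PRIMATE_LINEAGES: tuple[str, ...] = (
    "H_sapiens",
    "Hominini",
    "Homininae",
    "Hominidae",
    "Hominoidea",
    "Catarrhini",
    "Simiiformes",
    "Haplorrhini",
)

#: Developmental windows spanning 12 post-conception weeks to 64 post-natal
#: years. w5 = 35 pcw–0.3 py (late fetal/neonatal), w6 = 0.5–2.5 py (late
#: infancy to early childhood), w7 = 2.8–10.7 py (childhood), w8 = 13 py onward.
DEFAULT_WINDOWS: tuple[str, ...] = ("w1", "w2", "w3", "w4", "w5", "w6", "w7", "w8")

EXPRESSION_UNITS = ("counts", "TPM", "normalized")

#: TPM columns must total one million within this relative tolerance.
TPM_COLUMN_TOTAL = 1e6
TPM_RTOL = 1e-6

METADATA_REQUIRED = ("sample_id", "region", "region_class")
REGION_CLASSES = ("cortical", "non_cortical", "other")


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x samples expression values with a units flag.

    Parameters
    ----------
    values
        DataFrame with unique gene ids on the index and unique sample ids on
        the columns; entries are finite and nonnegative.
    units
        One of ``counts``, ``TPM`` or ``normalized``. For ``TPM`` every
        non-empty column must total 1e6 within relative 1e-6; all-zero columns
        are permitted and recorded in :attr:`zero_columns`.
    """

    values: pd.DataFrame
    units: str = "normalized"
    zero_columns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.units not in EXPRESSION_UNITS:
            raise ValidationError(
                f"unknown units {self.units!r}; expected one of {EXPRESSION_UNITS}"
            )
        df = self.values
        dup_genes = _duplicates(df.index)
        if dup_genes:
            raise ValidationError(f"duplicate gene ids: {dup_genes}")
        dup_samples = _duplicates(df.columns)
        if dup_samples:
            raise ValidationError(f"duplicate sample ids: {dup_samples}")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            bad = df.columns[(arr < 0).any(axis=0)].tolist()
            raise ValidationError(f"negative expression values in samples: {bad}")
        colsums = arr.sum(axis=0)
        zero = tuple(df.columns[colsums == 0])
        if zero and not self.zero_columns:
            self.zero_columns = zero
        if self.units == "TPM":
            nz = colsums > 0
            off = np.abs(colsums[nz] - TPM_COLUMN_TOTAL) > TPM_RTOL * TPM_COLUMN_TOTAL
            if off.any():
                bad = df.columns[nz][off].tolist()
                raise ValidationError(
                    f"TPM columns must sum to 1e6 (relative {TPM_RTOL}); offenders: {bad[:5]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), units=self.units)


@dataclass
class GeneEvoTable:
    """Per-gene dN/dS across ordered ancestral lineages plus gene age.

    ``data`` is indexed by gene id with one float column per lineage (NaN marks
    a missing dN/dS estimate for that gene/lineage pair) and an ``age`` column
    in time before present (e.g. Mya; larger = older; NaN allowed).
    """

    data: pd.DataFrame
    lineages: tuple[str, ...] = PRIMATE_LINEAGES

    AGE_COLUMN = "age"

    def __post_init__(self) -> None:
        self.lineages = tuple(self.lineages)
        if len(set(self.lineages)) != len(self.lineages):
            raise ValidationError("lineage labels must be unique")
        dup = _duplicates(self.data.index)
        if dup:
            raise ValidationError(f"duplicate gene ids: {dup}")
        missing_cols = [c for c in self.lineages if c not in self.data.columns]
        if missing_cols:
            raise ValidationError(f"missing lineage columns: {missing_cols}")
        for lin in self.lineages:
            col = self.data[lin]
            if (col.dropna() < 0).any():
                raise ValidationError(f"negative dN/dS values in lineage {lin!r}")
        if self.AGE_COLUMN in self.data.columns:
            ages = self.data[self.AGE_COLUMN].dropna()
            if not np.isfinite(ages.to_numpy(dtype=float)).all():
                raise ValidationError("gene ages must be finite where present")
            if (ages < 0).any():
                raise ValidationError("gene ages must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def dnds(self, lineage: str) -> pd.Series:
        if lineage not in self.lineages:
            raise ValidationError(
                f"unknown lineage {lineage!r}; expected one of {list(self.lineages)}"
            )
        return self.data[lineage]

    @property
    def ages(self) -> pd.Series:
        if self.AGE_COLUMN not in self.data.columns:
            raise ValidationError("gene evo table carries no age column")
        return self.data[self.AGE_COLUMN]


def validate_sample_metadata(
    meta: pd.DataFrame, require_mapping_stats: bool = False
) -> pd.DataFrame:
    """Validate a sample-metadata table and return it unchanged.

    Required columns: sample_id (unique), region, region_class. Optional:
    window, cell_type, uniquely_mapped_reads, total_reads. When
    ``require_mapping_stats`` both read-count columns must be present and
    non-missing on every row, with uniquely_mapped_reads <= total_reads.
    """
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    dup = _duplicates(meta["sample_id"])
    if dup:
        raise ValidationError(f"duplicate sample ids in metadata: {dup}")
    bad_class = sorted(set(meta["region_class"]) - set(REGION_CLASSES))
    if bad_class:
        raise ValidationError(
            f"unknown region_class values {bad_class}; expected {REGION_CLASSES}"
        )
    if require_mapping_stats:
        for col in ("uniquely_mapped_reads", "total_reads"):
            if col not in meta.columns:
                raise ValidationError(f"metadata missing mapping-stat column {col!r}")
            if meta[col].isna().any():
                rows = meta.loc[meta[col].isna(), "sample_id"].tolist()
                raise ValidationError(f"missing {col} for samples: {rows[:5]}")
        if (meta["total_reads"] <= 0).any():
            raise ValidationError("total_reads must be positive")
        over = meta["uniquely_mapped_reads"] > meta["total_reads"]
        if over.any():
            rows = meta.loc[over, "sample_id"].tolist()
            raise ValidationError(
                f"uniquely_mapped_reads exceeds total_reads for samples: {rows[:5]}"
            )
    return meta


INDEX_TABLE_COLUMNS = ("group", "lineage", "index_kind", "value", "n_genes_used")


def validate_index_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format index table invariants (finite values, unique keys)."""
    missing = [c for c in INDEX_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"index table missing columns: {missing}")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValidationError("index values must be finite")
    if (table["n_genes_used"] < 1).any():
        raise ValidationError("n_genes_used must be >= 1")
    key = table[["group", "lineage", "index_kind"]].astype(object).fillna("")
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValidationError(f"duplicate (group, lineage, index_kind) key: {dup}")
    return table
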