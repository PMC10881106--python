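"""Tabular I/O, sample QC, TPM normalization and group aggregation.

File dialects
-------------
* expression TSV: header row, gene id in the first column, one column per sample
* GCT v1.2 (read-only): ``#1.2`` line, ``<n_genes>\\t<n_samples>`` line, then a
  table whose first two columns are Name and Description
* gene-evo TSV: columns ``gene_id``, one per lineage, ``age``
* metadata TSV: one row per sample

All writers emit UTF-8 with LF line endings.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    PRIMATE_LINEAGES,
    ExpressionMatrix,
    GeneEvoTable,
    validate_sample_metadata,
)
from .errors import ParseError, ValidationError

# QC thresholds used in the macaque reprocessing: samples are retained when
# uniquely mapped reads strictly exceed 10 million AND the uniquely mapped
# fraction strictly exceeds 80%.
DEFAULT_MIN_UNIQUE_READS = 10_000_000
DEFAULT_MIN_UNIQUE_FRACTION = 0.8


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse {path} as TSV: {exc}") from exc


def read_expression_matrix(
    path: str | Path, format: str = "tsv", units: str = "normalized"
) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV or GCT v1.2.

    ``units`` is taken from the caller (files carry no units metadata in
    either dialect). Duplicate gene ids and negative entries are rejected.
    """
    path = Path(path)
    if format == "tsv":
        df = _read_table(path)
        if df.shape[1] < 2:
            raise ParseError(f"{path}: expected gene id column plus >=1 sample column")
        df = df.set_index(df.columns[0])
    elif format == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(f"{path}: line 1: expected GCT version '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ParseError(f"{path}: line 2: expected '<n_genes>\\t<n_samples>'")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", dtype={0: str})
        if df.shape[0] != n_genes or df.shape[1] - 2 != n_samples:
            raise ParseError(
                f"{path}: declared {n_genes}x{n_samples} but found "
                f"{df.shape[0]}x{df.shape[1] - 2}"
            )
        df = df.set_index(df.columns[0]).drop(columns=[df.columns[1]])
    else:
        raise ValidationError(f"unknown expression format {format!r}; expected tsv or gct")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return ExpressionMatrix(df, units=units)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def read_gene_evo_table(
    path: str | Path, lineages: Sequence[str] = PRIMATE_LINEAGES
) -> GeneEvoTable:
    """Read a gene-evo TSV (gene_id, one dN/dS column per lineage, age).

    Empty cells stay missing (NaN), never zero. A dN/dS column outside the
    configured lineage list is an error listing the expected labels.
    """
    df = _read_table(path)
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: first column must be 'gene_id'")
    df = df.set_index("gene_id")
    known = set(lineages) | {GeneEvoTable.AGE_COLUMN}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValidationError(
            f"unknown lineage columns {unknown}; expected labels {list(lineages)}"
        )
    return GeneEvoTable(df.astype(float), lineages=tuple(lineages))


def write_gene_evo_table(table: GeneEvoTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    return validate_sample_metadata(df)


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def qc_filter_samples(
    meta: pd.DataFrame,
    min_unique_reads: int = DEFAULT_MIN_UNIQUE_READS,
    min_unique_fraction: float = DEFAULT_MIN_UNIQUE_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain samples passing both mapping-quality criteria (strict ``>``).

    Returns ``(retained, rejection_log)``. The rejection log has one row per
    rejected sample with boolean columns ``fail_unique_reads`` and
    ``fail_unique_fraction`` attributing the failure to each criterion.
    Missing mapping stats raise rather than silently pass.
    """
    validate_sample_metadata(meta, require_mapping_stats=True)
    unique = meta["uniquely_mapped_reads"].to_numpy(dtype=float)
    total = meta["total_reads"].to_numpy(dtype=float)
    fail_reads = ~(unique > min_unique_reads)
    fail_frac = ~(unique / total > min_unique_fraction)
    keep = ~(fail_reads | fail_frac)
    log = pd.DataFrame(
        {
            "sample_id": meta["sample_id"].to_numpy(),
            "uniquely_mapped_reads": meta["uniquely_mapped_reads"].to_numpy(),
            "total_reads": meta["total_reads"].to_numpy(),
            "fail_unique_reads": fail_reads,
            "fail_unique_fraction": fail_frac,
        }
    )[~keep].reset_index(drop=True)
    return meta[keep].reset_index(drop=True), log


def counts_to_tpm(
    counts: ExpressionMatrix, gene_lengths: Mapping[str, float] | pd.Series
) -> ExpressionMatrix:
    """Convert raw counts to TPM using per-gene lengths in bases.

    Per sample: rate_i = count_i / length_i, TPM_i = 1e6 * rate_i / sum(rate).
    All-zero samples are flagged (``zero_columns``) and left all-zero.
    """
    if counts.units != "counts":
        raise ValidationError(f"expected units='counts', got {counts.units!r}")
    lengths = pd.Series(gene_lengths, dtype=float)
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValidationError(f"genes without a length: {missing[:5]}")
    lengths = lengths.loc[counts.gene_ids]
    if (lengths <= 0).any() or not np.isfinite(lengths).all():
        bad = lengths.index[(lengths <= 0) | ~np.isfinite(lengths)].tolist()
        raise ValidationError(f"gene lengths must be positive and finite: {bad[:5]}")
    rates = counts.values.to_numpy(dtype=float) / lengths.to_numpy()[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    scale = np.where(zero, 1.0, totals)
    tpm = 1e6 * rates / scale
    tpm[:, zero] = 0.0
    out = pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(out, units="TPM", zero_columns=tuple(counts.values.columns[zero]))


def normalize_cpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalize each column to counts-per-million (no length term).

    The per-cell normalization applied to UMI matrices before pseudobulk
    averaging; all-zero columns are flagged and left at zero.
    """
    vals = expr.values.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    zero = totals == 0
    out = 1e6 * vals / np.where(zero, 1.0, totals)
    out[:, zero] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        units="normalized",
        zero_columns=tuple(expr.values.columns[zero]),
    )


GROUPINGS = {
    "region": ("region",),
    "window": ("window",),
    "region_window": ("region", "window"),
    "cell_type": ("cell_type",),
    "region_cell_type": ("region", "cell_type"),
}

#: Separator joining the parts of a composite group label, e.g. "AMY|w6".
GROUP_SEP = "|"


def aggregate_expression(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    group_by: str = "region",
    reducer: str = "mean",
) -> ExpressionMatrix:
    """Collapse samples to groups (genes x groups), reducing by mean per gene.

    ``group_by`` is one of region, window, region_window, cell_type,
    region_cell_type; composite labels are joined with ``|``. Groups are
    ordered lexicographically so output is deterministic. ``reducer`` may be
    ``mean`` (default; keeps the group index interpretable as a weighted mean)
    or ``median``.
    """
    if group_by not in GROUPINGS:
        raise ValidationError(f"unknown grouping {group_by!r}; expected {sorted(GROUPINGS)}")
    if reducer not in ("mean", "median"):
        raise ValidationError(f"unknown reducer {reducer!r}")
    validate_sample_metadata(meta)
    cols = GROUPINGS[group_by]
    for c in cols:
        if c not in meta.columns:
            raise ValidationError(f"metadata lacks column {c!r} needed for grouping")
    meta_idx = meta.set_index("sample_id")
    missing = [s for s in expr.sample_ids if s not in meta_idx.index]
    if missing:
        raise ValidationError(f"expression samples absent from metadata: {missing[:5]}")
    sub = meta_idx.loc[expr.sample_ids, list(cols)]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValidationError(f"samples with missing {cols} labels: {bad[:5]}")
    labels = sub.astype(str).agg(GROUP_SEP.join, axis=1)
    if labels.empty:
        raise ValidationError("no samples to aggregate")
    grouped = expr.values.T.groupby(labels.to_numpy())
    agg = grouped.mean() if reducer == "mean" else grouped.median()
    agg = agg.sort_index().T
    units = expr.units if expr.units != "TPM" else "normalized"
    return ExpressionMatrix(agg, units=units)
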