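"""Expression-weighted evolutionary indices.

Two statistics share one kernel, the expression-weighted mean of a per-gene
quantity over a tissue/group:

* ERI (evolutionary rate index): values are per-gene dN/dS for one ancestral
  lineage, weights are the group's expression. High ERI = the group's
  transcriptome is enriched for rapidly evolving genes on that lineage.
* TAI (transcriptome age index): values are per-gene evolutionary ages (time
  since origin). Low TAI = enrichment for evolutionarily young genes.

Genes with a missing value are excluded pairwise (per lineage for ERI); no
expression cutoff is applied — every expressed gene contributes with its
untransformed expression weight.
"""
from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneEvoTable, validate_index_table
from .errors import UndefinedIndexError, ValidationError


class WeightedIndexResult(NamedTuple):
    value: float
    n_used: int


def weighted_index(values: Sequence[float], weights: Sequence[float]) -> WeightedIndexResult:
    """Weighted mean sum(v_i * w_i) / sum(w_i) with pairwise exclusion.

    Entries where the value is missing (NaN) or the weight is zero/missing are
    dropped before the ratio is formed; the count of retained entries is
    reported. Raises :class:`UndefinedIndexError` when nothing remains or the
    retained weights sum to zero, and :class:`ValidationError` on negative
    weights or length mismatch.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValidationError(f"length mismatch: {v.shape} values vs {w.shape} weights")
    if (w[~np.isnan(w)] < 0).any():
        raise ValidationError("weights must be nonnegative")
    keep = ~np.isnan(v) & ~np.isnan(w) & (w > 0)
    n = int(keep.sum())
    if n == 0:
        raise UndefinedIndexError("no entries retained (all values missing or weights zero)")
    total = w[keep].sum()
    if not total > 0:
        raise UndefinedIndexError("retained weights sum to zero")
    return WeightedIndexResult(float(np.dot(v[keep], w[keep]) / total), n)


def _index_table(
    gene_evo: GeneEvoTable,
    grouped_expr: ExpressionMatrix,
    kind: str,
) -> pd.DataFrame:
    shared = gene_evo.data.index.intersection(grouped_expr.values.index)
    if len(shared) == 0:
        raise ValidationError("no genes shared between gene evo table and expression matrix")
    expr = grouped_expr.values.loc[shared]
    groups = list(expr.columns)
    value_cols = list(gene_evo.lineages) if kind == "ERI" else [GeneEvoTable.AGE_COLUMN]
    if kind == "TAI":
        gene_evo.ages  # raises if absent

    rows = []
    W = expr.to_numpy(dtype=float)
    for col in value_cols:
        v = gene_evo.data.loc[shared, col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        vv, ww = v[ok], W[ok, :]
        used = ww > 0
        n_used = used.sum(axis=0)
        totals = ww.sum(axis=0)
        for j, g in enumerate(groups):
            if n_used[j] == 0 or not totals[j] > 0:
                lin = f" lineage {col!r}" if kind == "ERI" else ""
                raise UndefinedIndexError(
                    f"{kind} undefined for group {g!r}{lin}: zero total retained weight"
                )
        vals = (vv @ ww) / totals
        for j, g in enumerate(groups):
            rows.append(
                {
                    "group": g,
                    "lineage": col if kind == "ERI" else pd.NA,
                    "index_kind": kind,
                    "value": vals[j],
                    "n_genes_used": int(n_used[j]),
                }
            )
    table = pd.DataFrame(rows)
    return validate_index_table(table)


def compute_eri_table(
    gene_evo: GeneEvoTable, grouped_expr: ExpressionMatrix
) -> pd.DataFrame:
    """One ERI per (group x lineage), long format.

    Genes with a missing dN/dS in a lineage are excluded pairwise for that
    lineage only; ``n_genes_used`` records the retained gene count per cell.
    """
    return _index_table(gene_evo, grouped_expr, "ERI")


def compute_tai_table(
    gene_evo: GeneEvoTable, grouped_expr: ExpressionMatrix
) -> pd.DataFrame:
    """One TAI per group (lineage field empty), long format."""
    return _index_table(gene_evo, grouped_expr, "TAI")


def compute_index_table(
    gene_evo: GeneEvoTable, grouped_expr: ExpressionMatrix, kind: str
) -> pd.DataFrame:
    if kind not in ("ERI", "TAI"):
        raise ValidationError(f"unknown index kind {kind!r}")
    return _index_table(gene_evo, grouped_expr, kind)


def per_sample_index_table(
    gene_evo: GeneEvoTable,
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    kind: str,
    group_by: str = "region",
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Index-per-sample-then-average alternative to aggregate-then-index.

    Computes the index for every sample separately, averages within groups,
    and (optionally) attaches percentile bootstrap confidence intervals over
    the member samples (``n_boot`` resamples, seeded). Columns: group,
    lineage, index_kind, value, n_genes_used (minimum over member samples),
    n_samples[, ci_low, ci_high].
    """
    from .io_qc import GROUP_SEP, GROUPINGS  # local import to avoid cycle

    if group_by not in GROUPINGS:
        raise ValidationError(f"unknown grouping {group_by!r}")
    per_sample = _index_table(gene_evo, expr, kind)
    cols = list(GROUPINGS[group_by])
    meta_idx = meta.set_index("sample_id")
    missing = [s for s in expr.sample_ids if s not in meta_idx.index]
    if missing:
        raise ValidationError(f"expression samples absent from metadata: {missing[:5]}")
    labels = meta_idx.loc[per_sample["group"], cols].astype(str).agg(GROUP_SEP.join, axis=1)
    per_sample = per_sample.assign(_grp=labels.to_numpy())
    rng = np.random.default_rng(seed)
    rows = []
    for (grp, lin), sub in per_sample.groupby(
        ["_grp", per_sample["lineage"].astype(object).fillna("")], sort=True
    ):
        vals = sub["value"].to_numpy()
        row = {
            "group": grp,
            "lineage": lin if lin else pd.NA,
            "index_kind": kind,
            "value": float(vals.mean()),
            "n_genes_used": int(sub["n_genes_used"].min()),
            "n_samples": len(vals),
        }
        if n_boot > 0:
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            boots = vals[idx].mean(axis=1)
            row["ci_low"] = float(np.percentile(boots, 2.5))
            row["ci_high"] = float(np.percentile(boots, 97.5))
        rows.append(row)
    return pd.DataFrame(rows)


def index_mode_discrepancy(
    gene_evo: GeneEvoTable,
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    kind: str,
    group_by: str = "region",
) -> pd.DataFrame:
    """Measure aggregate-then-index vs per-sample-then-average per group.

    The two agree exactly only when every member sample carries the same total
    weight; the difference is reported, not hidden.
    """
    from .io_qc import aggregate_expression

    agg = compute_index_table(gene_evo, aggregate_expression(expr, meta, group_by), kind)
    per = per_sample_index_table(gene_evo, expr, meta, kind, group_by)
    key = ["group", "lineage"]
    merged = agg.merge(
        per[key + ["value", "n_samples"]], on=key, suffixes=("_aggregate", "_per_sample")
    )
    merged["discrepancy"] = merged["value_aggregate"] - merged["value_per_sample"]
    return merged


def write_index_table(table: pd.DataFrame, path) -> None:
    validate_index_table(table)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_index_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_index_table(table)
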