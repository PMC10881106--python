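"""Inferential layer: class comparisons, correlation diagnostics, trajectory
peaks and simulation-based calibration.

The headline comparison is a per-lineage two-sample t-test of per-region ERI
values between non-cortical and cortical regions (Welch by default; the class
variances have no reason to be equal). A Benjamini-Hochberg column is emitted
alongside the raw per-lineage p-values. The correlation diagnostic checks
that per-gene dN/dS and expression are only weakly correlated, so the index
is not driven by an expression-rate confound. Developmental trajectories are
summarized by their peak window (ERI) or trough window (TAI).
"""
from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix, GeneEvoTable, validate_index_table
from .errors import ValidationError
from .io_qc import GROUP_SEP, aggregate_expression
from .indices import compute_eri_table
from .synthetic import SimConfig, simulate_expression_study, simulate_gene_evo

T_TEST_METHODS = ("welch", "student")
SIDEDNESS = ("two_sided", "greater")

COMPARISON_COLUMNS = (
    "lineage",
    "mean_noncortical",
    "mean_cortical",
    "t_statistic",
    "degrees_of_freedom",
    "p_value",
    "p_value_bh",
    "method",
    "sidedness",
    "n_noncortical",
    "n_cortical",
)


def compare_region_classes(
    index_table: pd.DataFrame,
    class_map: Mapping[str, str],
    method: str = "welch",
    sidedness: str = "two_sided",
) -> pd.DataFrame:
    """Per-lineage t-test of per-region ERI between the two region classes.

    ``index_table`` is a long ERI table with one row per (region, lineage);
    ``class_map`` sends each region to cortical / non_cortical / other
    ("other" regions are excluded). The alternative for ``greater`` is
    non-cortical > cortical. Degenerate all-equal inputs give t=0, p=1
    rather than NaN. Raises if any class has fewer than two regions.
    """
    if method not in T_TEST_METHODS:
        raise ValidationError(f"unknown method {method!r}; expected {T_TEST_METHODS}")
    if sidedness not in SIDEDNESS:
        raise ValidationError(f"unknown sidedness {sidedness!r}; expected {SIDEDNESS}")
    validate_index_table(index_table)
    table = index_table[index_table["index_kind"] == "ERI"]
    if table.empty:
        raise ValidationError("index table contains no ERI rows")
    unknown = sorted(set(table["group"]) - set(class_map))
    if unknown:
        raise ValidationError(f"regions without a class label: {unknown[:5]}")

    rows = []
    for lineage, sub in table.groupby("lineage", sort=False):
        cls = sub["group"].map(class_map)
        nc = sub.loc[cls == "non_cortical", "value"].to_numpy(dtype=float)
        c = sub.loc[cls == "cortical", "value"].to_numpy(dtype=float)
        if len(nc) < 2 or len(c) < 2:
            raise ValidationError(
                f"lineage {lineage!r}: need >=2 regions per class "
                f"(got {len(nc)} non-cortical, {len(c)} cortical)"
            )
        t, df, p = _two_sample_t(nc, c, method, sidedness)
        rows.append(
            {
                "lineage": lineage,
                "mean_noncortical": float(nc.mean()),
                "mean_cortical": float(c.mean()),
                "t_statistic": t,
                "degrees_of_freedom": df,
                "p_value": p,
                "method": method,
                "sidedness": sidedness,
                "n_noncortical": len(nc),
                "n_cortical": len(c),
            }
        )
    out = pd.DataFrame(rows)
    out.insert(
        out.columns.get_loc("p_value") + 1,
        "p_value_bh",
        sps.false_discovery_control(out["p_value"].to_numpy(), method="bh"),
    )
    return out


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, method: str, sidedness: str
) -> tuple[float, float, float]:
    se2 = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
    if se2 == 0.0:
        # degenerate: zero variance in both groups
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        t = np.inf if a.mean() > b.mean() else -np.inf
        p = 0.0 if (sidedness == "two_sided" or t > 0) else 1.0
        return float(t), df, float(p)
    alt = "two-sided" if sidedness == "two_sided" else "greater"
    res = sps.ttest_ind(a, b, equal_var=(method == "student"), alternative=alt)
    return float(res.statistic), float(res.df), float(res.pvalue)


CORRELATION_TRANSFORMS = ("identity", "log1p")


def dnds_expression_correlation(
    gene_evo: GeneEvoTable,
    grouped_expr: ExpressionMatrix,
    transform: str = "identity",
) -> pd.DataFrame:
    """Pearson r between per-gene dN/dS and (transformed) group expression.

    One row per (group, lineage) with pairwise missing exclusion. Zero
    variance in either vector, or fewer than 3 complete pairs, yields a
    flagged row (``undefined`` True, r = NaN) rather than an error.
    """
    if transform not in CORRELATION_TRANSFORMS:
        raise ValidationError(f"unknown transform {transform!r}")
    shared = gene_evo.data.index.intersection(grouped_expr.values.index)
    if len(shared) == 0:
        raise ValidationError("no genes shared between tables")
    expr = grouped_expr.values.loc[shared].to_numpy(dtype=float)
    if transform == "log1p":
        expr = np.log1p(expr)
    rows = []
    for lineage in gene_evo.lineages:
        v = gene_evo.data.loc[shared, lineage].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        for j, group in enumerate(grouped_expr.values.columns):
            e = expr[ok, j]
            vv = v[ok]
            n = len(vv)
            undefined = n < 3 or vv.std() == 0 or e.std() == 0
            r = float("nan") if undefined else float(sps.pearsonr(vv, e).statistic)
            rows.append(
                {
                    "group": group,
                    "lineage": lineage,
                    "pearson_r": r,
                    "n_genes": n,
                    "transform": transform,
                    "undefined": undefined,
                }
            )
    return pd.DataFrame(rows)


def peak_stage(
    index_table: pd.DataFrame,
    windows: Sequence[str],
    sep: str = GROUP_SEP,
) -> pd.DataFrame:
    """Peak (ERI) or trough (TAI) developmental window per region x lineage.

    ``index_table`` must be grouped by region x window (labels
    ``region<sep>window``). ERI trajectories are summarized by their argmax
    window, TAI by the argmin ("youngest" window); exact ties break toward
    the earliest window in the configured order. Unknown window labels are an
    error.
    """
    validate_index_table(index_table)
    windows = list(windows)
    if len(set(windows)) != len(windows) or not windows:
        raise ValidationError("window labels must be unique and non-empty")
    parts = index_table["group"].str.rsplit(sep, n=1)
    if (parts.str.len() != 2).any():
        bad = index_table.loc[parts.str.len() != 2, "group"].iloc[0]
        raise ValidationError(f"group label {bad!r} is not 'region{sep}window'")
    tbl = index_table.assign(
        region=parts.str[0], window=parts.str[1],
        lineage=index_table["lineage"].astype(object),
    )
    unknown = sorted(set(tbl["window"]) - set(windows))
    if unknown:
        raise ValidationError(f"unknown window labels {unknown}; expected order {windows}")

    rows = []
    for (region, lineage, kind), sub in tbl.groupby(
        ["region", tbl["lineage"].fillna(""), "index_kind"], sort=True
    ):
        series = sub.set_index("window")["value"].reindex(windows).dropna()
        if len(series) < 2:
            raise ValidationError(
                f"region {region!r} lineage {lineage!r}: need >=2 windows, got {len(series)}"
            )
        vals = series.to_numpy()
        if kind == "ERI":
            pos, direction = int(np.argmax(vals)), "peak"
        else:
            pos, direction = int(np.argmin(vals)), "trough"
        rows.append(
            {
                "region": region,
                "lineage": lineage if lineage else pd.NA,
                "index_kind": kind,
                "window": series.index[pos],
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def simulate_class_comparison(
    config: SimConfig, method: str = "welch", sidedness: str = "two_sided"
) -> pd.DataFrame:
    """One synthetic study end to end: simulate, aggregate by region, ERI,
    per-lineage class comparison. Returns the comparison table."""
    gene_evo = simulate_gene_evo(config)
    expr, meta, _ = simulate_expression_study(gene_evo, config)
    grouped = aggregate_expression(expr, meta, "region")
    eri = compute_eri_table(gene_evo, grouped)
    class_map = dict(config.regions)
    return compare_region_classes(eri, class_map, method=method, sidedness=sidedness)


def run_null_calibration(
    config: SimConfig,
    n_reps: int = 2000,
    alpha: float = 0.05,
    method: str = "welch",
    sidedness: str = "two_sided",
) -> dict:
    """Empirical type-I error of the full simulate->ERI->compare chain.

    ``config`` must carry ``coupling_delta=0`` (the null). Repeats the whole
    pipeline ``n_reps`` times with replicate seeds derived from the config
    seed and reports per-lineage rejection rates at ``alpha``, the
    min-over-lineages ("any lineage") rate, and Wilson 95% intervals.
    """
    if config.coupling_delta != 0.0:
        raise ValidationError("null calibration requires coupling_delta=0")
    if n_reps < 100:
        raise ValidationError("n_reps must be >= 100")
    rates = rejection_rates(config, n_reps, alpha, method, sidedness)
    return rates


def rejection_rates(
    config: SimConfig,
    n_reps: int,
    alpha: float,
    method: str = "welch",
    sidedness: str = "two_sided",
) -> dict:
    """Fraction of replicate studies with p < alpha, per lineage and overall."""
    lineages = list(config.lineages)
    hits = np.zeros(len(lineages))
    any_hits = 0
    for rep in range(n_reps):
        rep_config = replace(config, seed=int(np.random.SeedSequence(config.seed, spawn_key=(3, rep)).generate_state(1)[0] % (2**31)))
        comp = simulate_class_comparison(rep_config, method=method, sidedness=sidedness)
        p = comp.set_index("lineage").loc[lineages, "p_value"].to_numpy()
        hits += p < alpha
        any_hits += int((p < alpha).any())
    per_lineage = {lin: float(h / n_reps) for lin, h in zip(lineages, hits)}
    lo, hi = _wilson(hits.mean(), n_reps)
    return {
        "alpha": alpha,
        "n_reps": n_reps,
        "per_lineage_rate": per_lineage,
        "mean_rate": float(hits.mean() / n_reps),
        "any_lineage_rate": float(any_hits / n_reps),
        "mean_rate_ci95": [lo, hi],
        "method": method,
        "sidedness": sidedness,
    }


def _wilson(successes: float, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    p = successes / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return float(center - half), float(center + half)
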