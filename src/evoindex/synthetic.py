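"""Synthetic study generator.

Emulates the data structure of a primate brain evolutionary-transcriptomics
study: a per-gene table of dN/dS values on the eight nested ancestral lineages
leading to human plus a gene age; region-structured expression matrices with a
plantable coupling between dN/dS and expression that differs between cortical
and non-cortical regions; developmental-window structure with a planted peak;
mapping-statistic covariates with explicitly planted QC failures; and an
ortholog presence/absence matrix evolved by loss on a dated species tree.

Every planted quantity is recorded in :class:`SimTruth`, so each downstream
stage can be checked against ground truth. One seed governs a whole study;
sub-streams are derived with fixed spawn keys so composite fixtures are
reproducible bit for bit.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import DEFAULT_WINDOWS, PRIMATE_LINEAGES, ExpressionMatrix, GeneEvoTable
from .errors import ValidationError
from .gene_age import PresenceAbsence, SpeciesTree, focal_path_node_ages, focal_path_nodes, node_ages_from_tree

#: Dated primate tree whose focal-path nodes carry the eight ancestral
#: lineages (ages in Mya, approximate consensus divergence times), rooted with
#: the Chinese tree shrew as outgroup.
DEFAULT_TREE_NEWICK = (
    "((((((((Homo_sapiens:6.7,Pan_troglodytes:6.7)Hominini:2.3,"
    "Gorilla_gorilla:9.0)Homininae:7.0,Pongo_abelii:16.0)Hominidae:4.0,"
    "Nomascus_leucogenys:20.0)Hominoidea:9.0,Macaca_mulatta:29.0)Catarrhini:14.0,"
    "Callithrix_jacchus:43.0)Simiiformes:21.0,Tarsius_syrichta:64.0)Haplorrhini:10.0,"
    "Tupaia_belangeri:74.0)Root;"
)
DEFAULT_FOCAL = "Homo_sapiens"

#: Default study layout: 12 brain regions, half cerebral cortex, half
#: non-cortical structures (endocrine glands, brainstem, basal structures).
DEFAULT_REGIONS: tuple[tuple[str, str], ...] = (
    ("DLPFC", "cortical"),
    ("V1C", "cortical"),
    ("OFC", "cortical"),
    ("ACC", "cortical"),
    ("STG", "cortical"),
    ("M1C", "cortical"),
    ("HYP", "non_cortical"),
    ("PG", "non_cortical"),
    ("MED", "non_cortical"),
    ("HTH", "non_cortical"),
    ("CBC", "non_cortical"),
    ("STR", "non_cortical"),
)


def default_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(DEFAULT_TREE_NEWICK, focal=DEFAULT_FOCAL)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic study; defaults are the package's reference
    study conditions (see docs/methods.md for rationale).

    coupling_delta is the log-expression shift per unit of standardized dN/dS
    applied in non-cortical samples only (0 = null, no class difference);
    window_coupling scales an analogous shift whose amplitude peaks at
    peak_window, planting the developmental trajectory peak.
    """

    n_genes: int = 2000
    lineages: tuple[str, ...] = PRIMATE_LINEAGES
    regions: tuple[tuple[str, str], ...] = DEFAULT_REGIONS
    n_samples_per_region: int = 48
    coupling_delta: float = 0.5
    coupling_reference: str = "mean"  # "mean" or a lineage label
    windows: tuple[str, ...] = DEFAULT_WINDOWS
    peak_window: str = "w6"
    window_coupling: float = 0.6
    window_width: float = 0.8
    dnds_shape: float = 0.5
    dnds_scale: float = 0.4
    dnds_lineage_corr: float = 0.7
    dnds_missing_rate: float = 0.02
    age_coupling: float = 0.0
    expr_base_mean: float = 2.0
    expr_base_sd: float = 1.0
    expr_sigma: float = 1.0
    output_units: str = "normalized"  # or "counts"
    reads_mean: float = 3.0e7
    reads_dispersion: float = 20.0
    unique_frac_a: float = 60.0
    unique_frac_b: float = 9.0
    n_qc_fail: int = 0
    loss_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_region < 1:
            raise ValidationError("all counts must be >= 1")
        if len(set(self.lineages)) != len(self.lineages):
            raise ValidationError("lineage labels must be unique")
        if self.dnds_shape <= 0 or self.dnds_scale <= 0:
            raise ValidationError("gamma parameters dnds_shape/dnds_scale must be positive")
        if not np.isfinite(self.coupling_delta):
            raise ValidationError("coupling_delta must be finite")
        if not 0.0 <= self.loss_rate <= 1.0:
            raise ValidationError("loss_rate must lie in [0, 1]")
        if not 0.0 <= self.dnds_missing_rate < 1.0:
            raise ValidationError("dnds_missing_rate must lie in [0, 1)")
        if not 0.0 <= self.dnds_lineage_corr < 1.0:
            raise ValidationError("dnds_lineage_corr must lie in [0, 1)")
        if self.expr_sigma <= 0 or self.expr_base_sd < 0:
            raise ValidationError("expression noise scales must be positive")
        if self.peak_window not in self.windows:
            raise ValidationError(f"peak_window {self.peak_window!r} not in windows")
        if self.coupling_reference != "mean" and self.coupling_reference not in self.lineages:
            raise ValidationError(
                f"coupling_reference must be 'mean' or a lineage label, got {self.coupling_reference!r}"
            )
        if self.output_units not in ("normalized", "counts"):
            raise ValidationError("output_units must be 'normalized' or 'counts'")
        for _, cls in self.regions:
            if cls not in ("cortical", "non_cortical", "other"):
                raise ValidationError(f"unknown region class {cls!r}")
        if self.n_qc_fail > len(self.regions) * self.n_samples_per_region:
            raise ValidationError("n_qc_fail exceeds the number of samples")


@dataclass
class SimTruth:
    """Ground truth planted by the generator."""

    true_class_effect: float = float("nan")
    true_gene_ages: dict[str, float] = field(default_factory=dict)
    true_peak_window: str | None = None
    qc_failures: dict[str, str] = field(default_factory=dict)  # sample -> criterion
    per_lineage_class_effect: dict[str, float] = field(default_factory=dict)
    true_origin_nodes: dict[str, str] = field(default_factory=dict)


def _rng(config: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


def simulate_gene_evo(config: SimConfig, tree: SpeciesTree | None = None) -> GeneEvoTable:
    """Simulate the per-gene evolutionary table.

    Per lineage, dN/dS is marginally Gamma(dnds_shape, dnds_scale); a Gaussian
    copula with latent correlation ``dnds_lineage_corr`` shares a per-gene
    constraint factor across lineages (purifying selection is gene-specific,
    so real per-gene dN/dS is strongly correlated across nested lineages; set
    the correlation to 0 for fully independent lineages). A fraction
    ``dnds_missing_rate`` of cells is set missing. Gene ages are drawn
    uniformly from the node ages on the focal path of the dated species tree,
    optionally rank-coupled to the gene's mean dN/dS via ``age_coupling``.
    """
    tree = tree or default_tree()
    rng = _rng(config, 0)
    n, L = config.n_genes, len(config.lineages)
    rho = config.dnds_lineage_corr
    shared = rng.standard_normal(n)
    private = rng.standard_normal((n, L))
    latent = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * private
    dnds = sps.gamma.ppf(sps.norm.cdf(latent), a=config.dnds_shape, scale=config.dnds_scale)
    if config.dnds_missing_rate > 0:
        mask = rng.random((n, L)) < config.dnds_missing_rate
        dnds = np.where(mask, np.nan, dnds)

    path_ages = np.asarray(focal_path_node_ages(tree))
    if config.age_coupling == 0.0:
        ages = rng.choice(path_ages, size=n)
    else:
        # Gaussian-copula rank coupling between age and the shared dN/dS factor
        rho_a = float(np.clip(config.age_coupling, -0.999, 0.999))
        latent_age = rho_a * shared + np.sqrt(1.0 - rho_a**2) * rng.standard_normal(n)
        qs = sps.norm.cdf(latent_age)
        ages = np.sort(path_ages)[np.minimum((qs * len(path_ages)).astype(int), len(path_ages) - 1)]

    gene_ids = [f"g{i:05d}" for i in range(n)]
    df = pd.DataFrame(dnds, index=pd.Index(gene_ids, name="gene_id"), columns=list(config.lineages))
    df[GeneEvoTable.AGE_COLUMN] = ages
    return GeneEvoTable(df, lineages=config.lineages)


def _coupling_score(gene_evo: GeneEvoTable, config: SimConfig) -> np.ndarray:
    """Standardized per-gene score the expression tilt is applied to."""
    if config.coupling_reference == "mean":
        z = gene_evo.data[list(config.lineages)].apply(
            lambda c: (c - c.mean()) / c.std(ddof=0), axis=0
        )
        score = z.mean(axis=1).to_numpy()
        score = np.where(np.isnan(score), 0.0, score)
    else:
        col = gene_evo.data[config.coupling_reference]
        score = ((col - col.mean()) / col.std(ddof=0)).to_numpy()
        score = np.where(np.isnan(score), 0.0, score)
    sd = score.std()
    return score / sd if sd > 0 else score


def _window_amplitude(config: SimConfig) -> np.ndarray:
    idx = np.arange(len(config.windows), dtype=float)
    peak = float(config.windows.index(config.peak_window))
    return config.window_coupling * np.exp(-0.5 * ((idx - peak) / config.window_width) ** 2)


def _expected_index(values: np.ndarray, log_weights: np.ndarray) -> float:
    ok = ~np.isnan(values)
    w = np.exp(log_weights[ok])
    return float(np.dot(values[ok], w) / w.sum())


def simulate_expression_study(
    gene_evo: GeneEvoTable, config: SimConfig
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate a region-structured expression study with planted effects.

    Expression is log-normal per gene per sample around a per-gene baseline.
    Non-cortical samples shift the mean log-expression of gene i by
    ``coupling_delta * score_i`` (score = standardized dN/dS summary), which
    tilts expression weight toward fast-evolving genes and plants a positive
    ERI excess. Windows are assigned round-robin within each region and add a
    ``window_amplitude(w) * score_i`` shift peaking at ``peak_window``.
    Mapping statistics are drawn conditioned to pass QC except for
    ``n_qc_fail`` explicitly planted failures (alternating criteria).
    """
    if not config.regions:
        raise ValidationError("region list must be non-empty")
    if len(gene_evo.gene_ids) != config.n_genes:
        raise ValidationError(
            f"gene evo table has {len(gene_evo.gene_ids)} genes, config expects {config.n_genes}"
        )
    rng = _rng(config, 1)
    n = config.n_genes
    score = _coupling_score(gene_evo, config)
    base = config.expr_base_mean + config.expr_base_sd * rng.standard_normal(n)
    amp = _window_amplitude(config)

    sample_ids: list[str] = []
    regions: list[str] = []
    classes: list[str] = []
    windows: list[str] = []
    cols: list[np.ndarray] = []
    for region, region_class in config.regions:
        for j in range(config.n_samples_per_region):
            w_idx = j % len(config.windows)
            mu = base + amp[w_idx] * score
            if region_class == "non_cortical":
                mu = mu + config.coupling_delta * score
            log_e = mu + config.expr_sigma * rng.standard_normal(n)
            cols.append(np.exp(log_e))
            sample_ids.append(f"{region}_s{j:03d}")
            regions.append(region)
            classes.append(region_class)
            windows.append(config.windows[w_idx])

    values = np.column_stack(cols)
    units = config.output_units
    if units == "counts":
        lengths = rng.integers(300, 20000, size=n).astype(float)
        p = values * lengths[:, None]
        p = p / p.sum(axis=0)
        depth = rng.integers(int(2e6), int(5e6), size=values.shape[1])
        values = rng.poisson(p * depth).astype(float)
    expr = ExpressionMatrix(
        pd.DataFrame(
            values,
            index=pd.Index(gene_evo.gene_ids, name="gene_id"),
            columns=sample_ids,
        ),
        units=units,
    )
    if units == "counts":
        expr.gene_lengths = pd.Series(lengths, index=gene_evo.gene_ids, name="length")

    n_samples = len(sample_ids)
    total, unique = _mapping_stats(rng, config, n_samples)
    fail_idx = rng.choice(n_samples, size=config.n_qc_fail, replace=False)
    qc_failures: dict[str, str] = {}
    for k, i in enumerate(sorted(fail_idx)):
        if k % 2 == 0:  # too few uniquely mapped reads, fraction still fine
            u = int(rng.integers(2_000_000, 10_000_001))
            unique[i], total[i] = u, int(u / 0.85)
            qc_failures[sample_ids[i]] = "unique_reads"
        else:  # enough reads but uniquely mapped fraction <= 80%
            u = int(rng.integers(11_000_000, 25_000_000))
            frac = rng.uniform(0.5, 0.79)
            unique[i], total[i] = u, int(np.ceil(u / frac))
            qc_failures[sample_ids[i]] = "unique_fraction"

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "region": regions,
            "region_class": classes,
            "window": windows,
            "cell_type": pd.NA,
            "uniquely_mapped_reads": unique,
            "total_reads": total,
        }
    )

    # planted class effect in expectation: weighted-mean difference using the
    # deterministic part of the log-weights (the sampling noise cancels)
    per_lineage: dict[str, float] = {}
    mean_amp = float(amp.mean())
    for lin in config.lineages:
        v = gene_evo.data[lin].to_numpy(dtype=float)
        e_nc = _expected_index(v, base + mean_amp * score + config.coupling_delta * score)
        e_c = _expected_index(v, base + mean_amp * score)
        per_lineage[lin] = e_nc - e_c
    truth = SimTruth(
        true_class_effect=float(np.mean(list(per_lineage.values()))),
        true_gene_ages=dict(zip(gene_evo.gene_ids, gene_evo.ages.to_numpy())),
        true_peak_window=config.peak_window,
        qc_failures=qc_failures,
        per_lineage_class_effect=per_lineage,
    )
    return expr, meta, truth


def _mapping_stats(
    rng: np.random.Generator, config: SimConfig, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (total, unique) read counts conditioned to pass the QC thresholds."""
    r = config.reads_dispersion
    p = r / (r + config.reads_mean)
    total = np.empty(n_samples, dtype=np.int64)
    unique = np.empty(n_samples, dtype=np.int64)
    for i in range(n_samples):
        for _ in range(200):
            t = int(rng.negative_binomial(r, p))
            f = float(rng.beta(config.unique_frac_a, config.unique_frac_b))
            u = int(t * f)
            if u > 10_000_000 and u / max(t, 1) > 0.8:
                break
        else:  # overwhelmingly unlikely; keep the sample valid regardless
            t, u = int(config.reads_mean), int(config.reads_mean * 0.85)
        total[i], unique[i] = t, u
    return total, unique


def simulate_presence_absence(
    tree: SpeciesTree, config: SimConfig
) -> tuple[PresenceAbsence, SimTruth]:
    """Evolve gene presence/absence by single origin + stochastic loss.

    Each gene originates at a node drawn uniformly from the focal path, is
    present in all leaves of that clade, and is then lost independently along
    each descendant branch with probability ``loss_rate``; a loss silences the
    whole subtree below. Branches on the path from the origin to the focal
    leaf never lose the gene, so every simulated gene is observable in the
    focal species.
    """
    rng = _rng(config, 2)
    path = focal_path_nodes(tree)
    ages = node_ages_from_tree(tree)
    leaves = tree.leaf_labels()
    path_ids = {id(n) for n in path}

    n = config.n_genes
    origin_idx = rng.integers(0, len(path), size=n)
    gene_ids = [f"g{i:05d}" for i in range(n)]
    mat = np.zeros((n, len(leaves)), dtype=bool)
    leaf_pos = {name: j for j, name in enumerate(leaves)}

    def descend(node, gene_row, protected: bool) -> None:
        if node.is_leaf():
            gene_row[leaf_pos[node.taxon.label]] = True
            return
        for child in node.child_nodes():
            child_protected = protected and id(child) in path_ids
            if not child_protected and rng.random() < config.loss_rate:
                continue
            descend(child, gene_row, child_protected)

    true_ages: dict[str, float] = {}
    true_nodes: dict[str, str] = {}
    for i in range(n):
        origin = path[origin_idx[i]]
        descend(origin, mat[i], protected=True)
        true_ages[gene_ids[i]] = float(ages[origin])
        label = origin.taxon.label if origin.taxon else (origin.label or "root")
        true_nodes[gene_ids[i]] = label

    pa = PresenceAbsence(
        pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=leaves)
    )
    truth = SimTruth(true_gene_ages=true_ages, true_origin_nodes=true_nodes)
    return pa, truth


def write_fixture_set(
    config: SimConfig, outdir: str | Path, tree: SpeciesTree | None = None
) -> dict[str, str]:
    """Generate and write a complete study fixture; returns the file manifest.

    Files: gene_evo.tsv, expression.tsv, metadata.tsv, tree.nwk,
    presence_absence.tsv, gene_lengths.tsv (counts mode only) and
    manifest.json recording the configuration and planted truth.
    """
    from . import io_qc

    tree = tree or default_tree()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_evo = simulate_gene_evo(config, tree)
    expr, meta, truth = simulate_expression_study(gene_evo, config)
    pa, pa_truth = simulate_presence_absence(tree, config)

    files = {
        "gene_evo": str(outdir / "gene_evo.tsv"),
        "expression": str(outdir / "expression.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "tree": str(outdir / "tree.nwk"),
        "presence_absence": str(outdir / "presence_absence.tsv"),
    }
    io_qc.write_gene_evo_table(gene_evo, files["gene_evo"])
    io_qc.write_expression_matrix(expr, files["expression"])
    io_qc.write_sample_metadata(meta, files["metadata"])
    Path(files["tree"]).write_text(tree.as_newick() + "\n", encoding="utf-8")
    pa.to_tsv(files["presence_absence"])
    if config.output_units == "counts":
        files["gene_lengths"] = str(outdir / "gene_lengths.tsv")
        expr.gene_lengths.rename_axis("gene_id").to_csv(
            files["gene_lengths"], sep="\t", lineterminator="\n", encoding="utf-8"
        )

    manifest = {
        "config": {k: _jsonable(v) for k, v in vars(config).items()},
        "focal": tree.focal,
        "files": files,
        "truth": {
            "true_class_effect": truth.true_class_effect,
            "per_lineage_class_effect": truth.per_lineage_class_effect,
            "true_peak_window": truth.true_peak_window,
            "qc_failures": truth.qc_failures,
            "presence_absence_true_ages": pa_truth.true_gene_ages,
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    files["manifest"] = str(outdir / "manifest.json")
    return files


def _jsonable(v):
    if isinstance(v, tuple):
        return [_jsonable(x) for x in v]
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def null_config(config: SimConfig) -> SimConfig:
    """The same study with every planted effect switched off."""
    return replace(config, coupling_delta=0.0, window_coupling=0.0)
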