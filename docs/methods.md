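# Methods

## The two indices

Both statistics are expression-weighted means of a per-gene evolutionary
quantity over the genes expressed in a tissue, developmental stage or cell
type:

- **Evolutionary rate index (ERI)** for a group *g* and ancestral lineage
  *l*:  ERI(g, l) = Σᵢ (dN/dS)ᵢ,ₗ · Eᵢ,g / Σᵢ Eᵢ,g, where (dN/dS)ᵢ,ₗ is the
  nonsynonymous/synonymous substitution-rate ratio of gene *i* on lineage *l*
  and Eᵢ,g is the gene's expression in the group. A high ERI means the
  group's transcriptome is dominated by rapidly evolving genes.
- **Transcriptome age index (TAI)** for a group *g*:
  TAI(g) = Σᵢ Aᵢ · Eᵢ,g / Σᵢ Eᵢ,g, where Aᵢ is the gene's evolutionary age
  (time before present since its origin). A low TAI means enrichment of
  evolutionarily young genes.

Conventions baked into `evoindex.indices`:

- Expression enters untransformed on the TPM/normalized scale — the formulas
  weight by E, not log E — and **no expression cutoff** is applied: a gene
  contributes exactly its (possibly tiny) expression weight.
- Genes with a missing dN/dS estimate are excluded **pairwise per lineage**,
  not listwise across lineages; the number of genes actually used is
  reported in every output row. An all-zero weight vector is a hard
  `UndefinedIndexError`, never a silent NaN.
- Both indices are invariant to rescaling a group's expression column and
  always lie inside [min, max] of the retained values (tested properties).

### Aggregate-then-index vs per-sample indices

The default path forms one expression profile per group (arithmetic mean of
member samples) and computes one index from it, matching one-value-per-area
reporting. The alternative — index per sample, then average within groups,
with seeded percentile-bootstrap confidence intervals — is exposed as
`per_sample_index_table` / `--index-mode per_sample`. The two agree exactly
only when all member samples have equal total weight;
`index_mode_discrepancy` measures and reports the difference rather than
hiding it. Group reduction by mean (median available) keeps the group index
interpretable as a weighted mean of gene-level values.

## Sample QC and normalization

Samples are retained when uniquely mapped reads **strictly exceed** 10
million and the uniquely mapped fraction **strictly exceeds** 80% (both
inequalities strict, matching the "greater than" wording of the protocol the
filter reproduces). The filter is idempotent, refuses rows with missing
mapping statistics, and emits a per-criterion rejection log. TPM conversion
is the standard two-step normalization (length first, then depth:
rateᵢ = countᵢ/lengthᵢ, TPMᵢ = 10⁶·rateᵢ/Σrate); columns then total 10⁶
within relative 10⁻⁶, all-zero columns are flagged and left at zero, and the
result is invariant to sequencing depth.

## Gene ages: simplified Dollo phylostratigraphy

`gene_age` assigns each focal-species gene the age of the most recent common
ancestor of the focal species and all carriers of the gene, on a dated
ultrametric species tree (node age = distance to descendant leaves;
ultrametricity is checked with tolerance 10⁻⁶ relative to tree height and
violations report the worst deviation). Assumptions: single origin, loss
allowed, no regain (Dollo), no horizontal transfer. Consequences, both
tested: ages only take values in the set of focal-path node ages; under a
loss-only generative process inference can only under-date, never over-date.
Genes private to the focal species are assigned age 0 (the youngest
stratum); any positive constant would be arbitrary, and every monotone
re-encoding (e.g. phylostratum ranks) preserves all order-level TAI
statements, which is all the trajectory analyses use.

The full homology-search phylostratigraphy pipelines used on real genomes
are out of scope; this module is the in-package dating step that the
synthetic presence/absence data exercises end to end.

## Inference layer

- **Class comparison**: per-lineage two-sample t-test of per-region ERI,
  non-cortical vs cortical. Welch by default (the class variances have no
  reason to be equal; Student behind a flag), two-sided by default (the
  directional claim is available as `greater` but a conservative default is
  used absent a stated one). Regions labelled `other` are excluded; a class
  with fewer than two regions is an error. Raw per-lineage p-values are
  reported; a Benjamini–Hochberg column is emitted alongside rather than
  replacing them. The degenerate all-equal case returns t = 0, p = 1.
- **Correlation diagnostic**: Pearson r between per-gene dN/dS and group
  expression (identity scale by default, log1p behind a flag, both written
  by the CLI), with pairwise missing exclusion; zero-variance inputs yield a
  flagged undefined row. Its purpose is negative control: if |r| were large,
  the index would partly restate an expression–rate confound.
- **Trajectory summary**: for each region × lineage, the ERI peak window
  (argmax) or TAI trough window (argmin) over the configured developmental
  window order, ties broken toward the earliest window.
- **Calibration**: `run_null_calibration` repeats the entire
  simulate → aggregate → ERI → compare chain under the null
  (`coupling_delta = 0`) and reports per-lineage empirical rejection rates
  with Wilson intervals; the companion power sweep does the same with a
  planted effect. These close the loop on the whole procedure, not just the
  t-test function.

## The synthetic-study generator

The generator produces every input the pipeline consumes, with recorded
ground truth (`SimTruth`), so each stage is verifiable without the original
datasets. What it emulates, and how:

- **dN/dS table**: per lineage, marginally Gamma(shape 0.5, scale 0.4) —
  mean 0.2, typical of genome-wide purifying selection, with a long tail —
  across the eight nested ancestral lineages from the terminal human branch
  to the haplorrhine stem. A Gaussian copula shares a per-gene constraint
  factor across lineages (latent correlation 0.7): purifying selection is
  gene-specific, so a gene slow on one lineage is slow on all. Setting the
  correlation to 0 gives fully independent lineages. 2% of cells are set
  missing. The copula leaves each lineage's marginal exactly gamma.
- **Gene ages**: drawn uniformly from the focal-path node ages of a dated
  primate tree (tree shrew outgroup, root 74 Mya), optionally rank-coupled
  to dN/dS (default correlation 0 so ERI and TAI tests stay orthogonal).
- **Expression**: log-normal per gene and sample around a per-gene baseline
  (log-mean spread 1.0, residual log-noise σ = 1.0). The planted class
  effect shifts non-cortical log-expression by `coupling_delta · scoreᵢ`,
  where scoreᵢ is the standardized per-gene mean of within-lineage dN/dS
  z-scores — a single tilt that propagates to every lineage's ERI through
  the cross-lineage correlation. The planted developmental effect adds an
  analogous tilt whose amplitude follows a Gaussian bump over the window
  order, peaking at the designated window. Expected planted ERI excesses are
  recorded per lineage in the truth object.
- **Mapping statistics**: total reads negative-binomial (mean 3×10⁷),
  uniquely mapped fraction Beta(60, 9), resampled so that non-planted
  samples pass QC by construction; QC failures are planted explicitly
  (alternating the two criteria) so expected counts are exact.
- **Presence/absence**: each gene originates at a uniform focal-path node
  and is lost independently per descendant branch with probability
  `loss_rate` (default 0.1); the focal lineage never loses the gene.

**Reference preset** (the `SimConfig` defaults): 2000 genes, 12 regions
(6 cortical / 6 non-cortical), 48 samples per region round-robined over 8
developmental windows (6 samples per region × window cell), planted class
effect `coupling_delta = 0.5`, planted peak at w6 with amplitude 0.6 and
bump width 0.8 windows. The sizes are deliberate downscales of the study
shapes the generator emulates (10,279 genes; hundreds of samples per region)
chosen so that the planted signals are reliably recoverable within a single
study while simulation sweeps stay cheap; the planted-peak recovery rate
under the preset was verified at 100% of region × lineage cells across 40
generator seeds. One seed governs a whole study; sub-streams use fixed
spawn keys.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: shared-ancestry correlation between regions of the
same brain, donor effects and batch structure, count overdispersion beyond
log-normal noise, expression–dN/dS confounding beyond the planted tilt
(real data show a weak negative correlation; the diagnostic is there to
measure it, not to reproduce it), incomplete ortholog detection other than
by branch loss, and any sequence-level process.

## Numerical and design choices

- Strict `>` in both QC criteria; boundary samples (exactly 10⁷ reads or
  exactly 80%) are removed.
- Welch degrees of freedom from the Welch–Satterthwaite formula via scipy;
  the test suite re-derives both t-tests from closed form independently and
  requires agreement to 10⁻¹⁰.
- Ultrametricity tolerance 10⁻⁶ (relative, with an absolute floor);
  tie-breaks in trajectory peaks go to the earliest window; group order is
  lexicographic everywhere so outputs are deterministic.
- Monte-Carlo problem sizes: type-I calibration uses 2000 replicate studies
  of 250 genes, 8+8 regions, 2 samples per region; the power sweep uses 200
  replicates of 400 genes, 20 non-cortical + 25 cortical regions, 4 samples
  per region. Sizes are the package's reference downscales; rates are
  reported with Wilson 95% intervals.
- CLI manifests contain no timestamps, so a rerun with identical inputs is
  byte-identical.

## Known limitations

- The class comparison treats regions as independent replicates; no
  phylogenetic or spatial correction across neighbouring regions is applied.
- Dollo dating under-dates in expectation when loss is present; the package
  quantifies the direction of the bias but does not correct it.
- The single-cell path is pseudobulk (mean normalized expression per cell
  type); no cell-level statistical model is provided.
- TAI comparisons are monotone-encoding-invariant but the absolute TAI scale
  depends on the age units supplied.
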