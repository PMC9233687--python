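# Methods

This note documents the models and procedures implemented in
`occultclone`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## scCNV processing and clone calling

**Consensus region CN.** Per-cell CNV segment calls are intersected with
mappable regions; the copy number of a region for a cell is the integer CN
covering the greatest number of bases of that region. Ties break to the
*lower* CN — a conservative choice against false amplification. Regions
shorter than 2 Mb or off the autosomes are dropped; a region with no
overlapping segment is an explicit missing value. The implementation is
interval arithmetic over sorted arrays; the test suite holds it equal to
an exhaustive per-base majority count on randomized instances.

**QC filters.** Cells flagged noisy by the instrument QC are always
removed. For gene-locus analyses, cells with mean ploidy < 1.5 (haploid
artifacts) are removed as well. For clone calling the haploid filter is
replaced by the ploidy-SD filter below.

**Arm profiles and ploidy.** Each cell's mean CN per chromosome arm is
the length-weighted average over its non-missing regions, with regions
straddling an arm boundary split at the boundary. Per-cell ploidy is the
median of length-weighted whole-chromosome means; cells farther than one
cohort standard deviation (population SD, ddof = 0) from the cohort mean
are excluded. The boundary is inclusive (|x − mean| ≤ SD), so a
zero-variance cohort is kept intact. Note this 1-SD filter is
intentionally aggressive — on a homogeneous near-Gaussian cohort it
removes roughly a third of cells — and is applied as stated.

**Clone definition.** Arm means are rounded to integers
(round-half-away-from-zero, stated explicitly because banker's rounding is
platform-convention-dependent) and arms where at least
`min_variant_fraction` (default 0.10) of cells differ from the modal
rounded CN become *discriminating arms*. Each distinct rounded-CN vector
over those arms is a clone; clones smaller than `min_clone_size` (default
20) leave their cells unassigned. Clone labels are ordered by decreasing
size then signature, making the partition invariant to cell order. An
explicit arm list (optionally with per-arm coordinate windows, e.g.
restricting 12q to 93.5–126.3 Mb) can replace the automated selection to
reproduce curated per-sample choices; `restrict_regions` implements the
windows at the region level.

**Pseudo-bulk profile and heterogeneity.** Per region the profile reports
the mean over cells of CN divided by the cell's own ploidy, and a
heterogeneity score: each cell is deleted (CN < ploidy − 0.5), amplified
(CN > ploidy + 0.5) or neutral, and heterogeneity is the Shannon entropy
of the three state frequencies divided by ln 3. The statistic is 0 exactly
when all cells share one state — in particular, uniform amplification at
*varying magnitude* still scores 0, matching the intended reading of a
near-zero heterogeneity track under a clonal amplification — and 1 for an
equal three-way split. The trichotomous-entropy choice is this package's
own definition of an otherwise unspecified plotted statistic.

**Gene-locus statistics.** Gene CN per cell is the same majority-bases
consensus over the gene interval. The amplified fraction of a gene is the
fraction of cells whose gene CN exceeds their mean ploidy + 1. A seeded
uniform subsample (default cap 1000 cells) feeds visualization tables;
fractions are always computed on all retained cells.

## Dosage model for clone assignment

Cells from an scRNA experiment are assigned to scCNV-derived clones by a
deliberately simple gene-dosage model. Given the gene × clone integer CN
matrix c (genes inside discriminating arms, CN differing between clones,
total UMI ≥ 20; cells with ≥ 100 UMI over those genes), cell n's counts
follow a mixture of multinomials with

    p_gc = μ_g c_gc / Σ_g' μ_g' c_g'c

over clones c, shared baseline rates μ on the unit simplex, and priors π.
EM: posteriors γ_nc ∝ π_c exp(Σ_g y_ng log p_gc) (log-space with
per-cell max subtraction); π updates to the mean posterior; μ updates by
the fixed point μ_g ← (Σ_n y_ng) / (Σ_n N_n Σ_c γ_nc c_gc / Z_c) and
renormalization. The fixed-point step is MM-style rather than an exact
maximizer, so the observed log-likelihood is additionally guarded by
geometric damping (the log-step is halved until the likelihood does not
decrease), making the recorded trace non-decreasing by construction.
Convergence: relative log-likelihood change < 1e-6 or 500 iterations;
initialization is μ ∝ pooled counts with π uniform, plus optional seeded
random restarts keeping the best likelihood.

Cells are assigned to the argmax-posterior clone only when that posterior
reaches the threshold (default 0.9; per-sample overrides, e.g. 0.5 for
low-confidence samples, live in the config). Exact posterior ties are
unassigned. Post-hoc merging of transcriptionally indistinguishable
clones is supported via a merge map. The model intentionally omits random
effects, covariates and overdispersion: it is a behavioural re-creation
of the dosage mechanism, not a bit-exact reimplementation of richer
variational treatments, and per-clone cell counts from such tools should
only be approximated, not matched.

## Phenotypic distance in rescaled diffusion space

All samples' cells are pooled; cells with ≥ 20% mitochondrial expression
(gene names `MT-*`) are dropped; counts are library-size normalized to
1e4, log1p-transformed, per-gene standardized and reduced to 30 principal
components (scanpy, arpack solver, fixed random state). A Euclidean kNN
graph (k = 30) gives affinities a_ij = exp(−d_ij²/(σ_i σ_j)) with the
adaptive bandwidth σ_i set to the distance to the ka-th neighbor,
ka = ⌈k/3⌉ (the kernel reference gives no parameter, this is the package's
default); σ is floored at the nearest positive neighbor distance when
duplicates occur. The affinity is symmetrized as (A + Aᵀ)/2 and rows
normalized to a Markov matrix P. Eigenpairs come from the symmetric
conjugate D^{−1/2} A D^{−1/2} (real spectrum, stable `eigsh` with a fixed
start vector); right eigenvectors of P are recovered as D^{−1/2} v with a
deterministic sign convention. The stationary λ=1 component is dropped and
coordinate i is multiplied by λ_i/(1 − λ_i) — the geometric-series weight
that turns one-step transition geometry into a multiscale diffusion
distance; the factor is pluggable. Default m = 10 components.

The distance between samples S and T is the mean Euclidean distance over
all cross pairs (i ∈ S, j ∈ T) in the rescaled space (optionally capped by
a seeded per-sample subsample); the within-sample diagonal is reported but
excluded from clustering. The cladogram is scipy average linkage on the
off-diagonal distances with samples pre-sorted lexicographically for
deterministic tie-breaks. The Pearson cross-check uses 1 − correlation of
per-sample mean log-normalized expression vectors.

When samples separate completely, the kNN graph disconnects and trailing
eigenvalues approach 1; λ is clipped at 1 − 1e-12, producing very large
(but finite and ordered) between-component distances. This is the correct
qualitative behaviour — disconnected samples are "infinitely" far — but
absolute distances in that regime should not be over-interpreted.

## Subtype assignment

Per cell, the average expression of each subtype gene set is computed on
library-size-normalized log1p expression (raw-count averaging is available
as an option; which scale the original scheme averaged is not stated, and
lognorm is the field-standard choice). The average divides by the full
set size, so set genes absent from the matrix contribute zero and are
recorded. The label is the set with the strictly highest average; exact
ties are unassigned for reproducibility. Support tables report, per
sample and label, the detection frequency of winning-set genes and flag
calls backed by fewer than a configurable number of detected genes — the
signature of cells "forced" into a subtype by one or two genes. Admixture
summaries give per-sample label fractions, and a per-cell hybrid flag
fires when every set's average exceeds a co-expression threshold. The
packaged GMT under `src/occultclone/data/` is a synthetic placeholder for
tests; real analyses must supply the published subtype gene lists.

## Differential expression and rank statistic

Markers between two cell groups are computed on log-normalized
expression: log fold change is the natural log of the ratio of de-logged
group means with pseudo-count 1; genes with |logFC| < 0.10 are excluded
before testing (and before the BH family is formed). The two-sided
Wilcoxon rank-sum p-value uses scipy's method="auto": exact enumeration
for small tie-free groups, normal approximation with tie correction
otherwise. FDR is Benjamini–Hochberg (statsmodels). The pre-ranked
enrichment input is s = −log10(FDR)·sign(logFC), with FDR = 0 capped at
±300 and descending sort with gene-name tie-break. Enrichment-score
computation itself is out of scope.

## Synthetic data generator

The generator defines the study conditions for every validation:

- **Clonal structure** — a clone tree on a configurable arm catalogue
  (hg19-like boundaries shipped as a data asset, or a toy 4-chromosome
  genome for fast tests); each child clone differs from its parent by
  exactly `events_per_clone` arm-level ±1 CN events on a uniform base
  ploidy (default triploid, 2 events — the arm-scale event sizes seen in
  cultured lines).
- **scCNV cells** — clone labels are multinomial in the clone
  frequencies; each cell emits one segment per mappable region at its
  clone's arm CN, with a `segment_noise_rate` fraction perturbed ±1
  (floored at 0). The ±1 model is an assumption; no noise model for
  segment calls is available to copy. `round(noisy_fraction·n_cells)`
  cells are flagged noisy and given region CN uniform in {0..8}, which is
  recognizably excluded by QC. The QC mean ploidy is the length-weighted
  mean of the emitted segments.
- **scRNA counts** — per-gene baselines μ_g are log-normal(0, 0.5);
  a cell of clone c draws multinomial counts with rate μ_g·cn(g, c) for
  dosage-coupled genes on copy-variant arms and μ_g·base_ploidy
  otherwise. Counts are multinomial given depth (no extra dispersion) to
  match the assignment model; a Dirichlet-multinomial switch exists for
  misspecification tests. Note the multinomial normalizer couples genes:
  the between-clone mean-count ratio of a dosage gene equals the CN ratio
  only when copy-variant genes are a small share of transcript mass.
- **Sample sets** — an ultrametric binary tree over sample names (nested
  tuples, unit height) drives Brownian perturbation of per-sample mean
  log-rates (variance ∝ branch length × `between_scale`, default 0.2);
  cells add i.i.d. Gaussian log-rate noise (`within_scale`, default 0.3)
  and draw multinomial counts at depth 2000 over 400 genes. The defaults
  place variants of the same parental line on one connected expression
  manifold while distinct lines separate — the regime the distance
  machinery is meant for. At much larger between-sample scales individual
  samples disconnect from the kNN graph and recovered topology becomes
  arbitrary, which the generator does not attempt to represent.

What the generator does *not* emulate: read-level noise, breakpoint
structure, doublets, batch effects, mitochondrial content (synthetic
cells carry no MT- genes, so the mito filter passes everything), and
realistic gene-length or GC biases. Passing tests therefore demonstrate
the correctness and statistical behaviour of the algorithms under the
stated generative assumptions, not performance on any real dataset.

## Problem sizes and determinism

The validation study uses 500 scCNV cells (3 clones at 0.5/0.3/0.2, 5%
segment noise), 1000 scRNA cells at depth 5000 over 200 copy-variant
genes, and 4 samples × 300 cells over 20 seeds for the hierarchy study —
sizes at which every effect being tested is comfortably resolved while
the whole suite runs in well under a minute per stage on one CPU. All
randomness is routed through numpy `SeedSequence`: the pipeline config
fans a single global seed into fixed per-stage child seeds (< 2^31), and
no computation path reads wall-clock or OS entropy, so identical configs
give byte-identical outputs.

## Known limitations

- Clone calling keys on arm-level rounded CN; focal events inside arms
  are only reachable through explicit coordinate windows.
- The ploidy-SD filter assumes a dominant ploidy mode; a cohort that is
  an even mixture of two ploidies would be halved.
- The dosage model ignores overdispersion; accuracy degrades gracefully
  under Dirichlet-multinomial misspecification (exercised in tests) but
  heavily overdispersed real data would warrant a dispersion term.
- Diffusion distances between disconnected graph components are dominated
  by the λ-clip and should be read as "effectively infinite" rather than
  metric.
- The Wilcoxon exact path is only taken for small tie-free groups; single
  cell data with heavy ties always uses the corrected normal
  approximation.
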