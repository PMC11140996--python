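# Methods

This note documents the statistical procedures implemented in `ctxneu`, the
synthetic data they are validated on, and the choices made where the
conventions were genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

All stages operate on an `anndata.AnnData`: raw integer counts in `X`
(cells × genes, CSR), per-cell metadata in `obs` (`patient`, `tissue`, and
— for synthetic data — `true_cell_type`, `true_is_malignant`,
`true_is_doublet`), and the gene annotation in `var` (`chromosome`,
`start_position`, `is_mitochondrial`). Log-normalization is the standard
transform throughout: counts scaled to 10,000 per cell, then `log(1+x)`,
cached in `layers["lognorm"]`.

## Synthetic multi-tissue generator (`ctxneu.simulate`)

The generator emulates the statistical structure of a multi-patient,
multi-region tumor study: each patient contributes one sample per tissue
(blood, peritumoral tissue, tumor), each sample a fixed number of cells.

**Count law.** Gene *g* has a baseline mean `m_g ~ LogNormal(μ₀, σ₀)`
(defaults μ₀ = 0, σ₀ = 1, i.e. a median of one count per gene per cell) and
counts are negative binomial with shared dispersion θ (variance
`m + m²/θ`). The default θ = 10 corresponds to a biological coefficient of
variation of ~0.32, typical of fitted UMI data; gene-specific dispersions
are deliberately not modelled.

**Programs.** A `GeneProgram` multiplies the means of its genes by
`2^log2_effect` in cells of its active tissues (optionally restricted to a
cell type). The default design plants three disjoint 30-gene neutrophil
programs — active in blood+peritumor, peritumor+tumor, and tumor only —
which are exactly the truth the three context scores are meant to recover,
plus marker programs separating neutrophils from epithelium. The
tumor-only program is additionally *half-induced* (`2^1.0`) in peritumor
via `partial_activation`: tissue reprogramming is a gradient, not a step,
and with strictly binary programs the peritumor-vs-blood ordering of the
Tumor-Modifying score would be decided by library-size normalization
artifacts rather than biology.

**Genome and CNV.** Genes sit at evenly spaced positions on 4 autosomes
plus a `chrM` contig holding the first ⌈1.3%⌉ of genes; CNV windowing only
needs ordering, so realistic coordinates are not attempted. A `CnvSegment`
multiplies the means of a contiguous gene run by its `copy_ratio` in
malignant cells; the default design plants one chromosome-scale gain
(370 genes, ratio 2.0 — an arm-level event, the typical carcinoma CNV)
carried by half of the tumor epithelial cells.

**Artifacts.** Doublets (default 5% per sample) sum two random same-sample
cells and are downsampled (multivariate hypergeometric) to the mean singlet
library size. Damaged cells (default 5%) have mitochondrial means inflated
so the expected mito fraction is 0.45, well above the 0.30 QC cut.

**Not modelled** (by design): batch effects, ambient RNA, UMI saturation,
gene-specific dispersion, spatial structure. Tests passing on this
generator therefore demonstrate correctness of the computations and
recoverability under idealised noise — not robustness to every artifact of
real data.

**Determinism.** One `numpy` generator seeded from the design drives every
draw; identical designs give bit-identical datasets, and the on-disk format
(Matrix Market triplet + TSV metadata) round-trips exactly.

## QC (`ctxneu.qc`)

A cell fails when it has fewer than 250 detected genes or more than 30%
mitochondrial counts — strict inequalities, so boundary cells (exactly 250
genes, exactly 30%) pass. "30% mitochondrial" is read as a fraction of
*counts*, not of detected genes — the common convention — and is computed
on raw counts before any normalization;
zero-count cells fail as `low_genes` rather than dividing by zero. When a
cell trips both filters, `low_genes` is recorded.

**Doublets.** The native scorer simulates doublets by summing two random
same-sample cells (no downsampling: the pooled matrix is library-size
normalized before embedding, which absorbs the doubled depth), pools them
with the observed cells, embeds everything by PCA of log-normalized counts
(30 components), and scores each observed cell by the fraction of its k
nearest pooled neighbours that are simulated. Defaults: k = 20, one
simulated doublet per four observed cells — a deliberately low simulation
ratio, because same-type ("embedded") simulated doublets are
indistinguishable from singlets and a large ratio would inflate every
singlet's score. An infinitesimal seeded jitter (10⁻⁹ of the embedding
scale) breaks exact kNN ties randomly, which matters only for degenerate
identical-expression inputs. The **consensus rule** is the actual
decision: a cell is removed only when at least two detectors flag it
(score ≥ threshold, default 0.5); external detectors' scores or 0/1 calls
enter through the same interface. Same-type doublets are largely invisible
to any expression-based detector, so recall is structurally limited; the
consensus rule instead protects singlets (specificity is the tested
guarantee).

## CNV malignancy score (`ctxneu.cnv`)

1. Genes with mean normalized expression below 0.1 across all cells are
   removed, as are chrM genes. The screening normalization rescales each
   cell to the *median* library size so the cutoff reads on the raw-count
   scale (the convention of expression-based CNV tools for droplet data).
2. Retained genes are log-normalized (fixed library 10,000, `log1p`),
   centred per gene on the mean over reference cells (normal epithelium),
   and clipped to ±3.
3. Within each chromosome, genes are sorted by start position and a
   100-gene window slides at stride 1 (`n − 99` windows; a chromosome with
   fewer than 100 retained genes contributes a single window of all its
   genes). CNVᵢ is the mean relative expression over window *i*.
4. Score = mean over windows of CNVᵢ²; a cell is malignant iff score
   > 0.04 (strictly).

The implementation is a sparse window-averaging operator applied to the
relative-expression matrix; the tests verify it against a literal
double-loop recomputation to 10⁻¹². No HMM smoothing or per-window state
calling is performed — the windowed score *is* the malignancy definition
here. Damaged high-mito cells depress all autosomal windows at once and
can score high; CNV calling is meant to run on QC-passing cells, as the
pipeline does.

## Differential expression (`ctxneu.dge`)

Per gene, log-normalized expression in a group is modelled as
`x = 0` with probability `1 − α`, `x ~ N(μ, σ²)` with probability `α`. All
MLEs are closed form: α is the detection fraction clamped to
`[10⁻⁵, 1 − 10⁻⁵]`, μ and σ² the mean and 1/n variance of the positive
values with a variance floor of 10⁻⁶ (degenerate all-identical groups then
fit with the floor instead of crashing). The statistic
`Λ = 2(ℓ_A + ℓ_B − ℓ_pooled)` is referred to χ²₃ (three parameters freed).
Using exact MLEs keeps Λ ≥ 0 and makes it reproducible by direct numerical
likelihood maximization (a test does exactly that); the popular R
implementation uses the n−1 sample standard deviation instead of the MLE,
which can produce slightly negative statistics — the MLE form is used
here.

Fold change is `(mean(expm1(x_A)) + ε) / (mean(expm1(x_B)) + ε)`,
ε = 10⁻⁹, i.e. a ratio of average de-logged expressions. A gene is
significant iff fold change > 1.2 **and** raw p < 0.001; no multiple-testing
correction enters the gate (a BH-adjusted column is emitted for
transparency). Tables are ranked by descending fold change, then ascending
p; ranking by p first is available (`rank_by="p"`). A Wilcoxon rank-sum
alternative is provided for sensitivity analysis.

## Context-dependent scores (`ctxneu.scores`)

Six directional DEG lists are computed among blood, peritumor and tumor
neutrophils (each "list" = genes passing both gates, i.e. up in the first
group). Then:

* Nontumor-Activating = up(peritumor vs tumor) ∩ up(blood vs tumor),
  ranked by the peritumor-vs-tumor fold change;
* Tissue-Residing = up(peritumor vs blood) ∩ up(tumor vs blood), ranked by
  the peritumor-vs-blood fold change;
* Tumor-Modifying = up(tumor vs peritumor) ∩ up(tumor vs blood), ranked by
  the tumor-vs-peritumor fold change.

Each set keeps the top 21 genes. The full significant lists are
intersected *first* and truncated *after* — the phrase "top N DEGs
intersected with…" is ambiguous, and this order guarantees every retained
gene satisfies both directional criteria; it also gives the prefix
property (smaller `top_n` yields a prefix of the larger set). Scores are
plain means of log-normalized expression over the set (a z-scored variant
is available); an empty intersection yields an empty set and a zero score
with a warning, not an error. Tissues may be supplied through a mapping
that pools multiple labels (e.g. adjacent liver and gallbladder) into
"peritumor".

**Signatures.** `build_signature` forms (significant DEGs up in subtype A
vs B) ∪ (genes with Pearson r to the anchor gene above a threshold, default
0.3) ∪ {anchor}. A constant anchor disables the correlation arm with a
warning. The resulting set size is data-dependent and is not a contract.

## Ro/e (`ctxneu.pref`)

Observed cluster × tissue counts versus `expected_ij = row_i·col_j / N`
(via `scipy.stats.contingency.expected_freq`); Ro/e is the elementwise
ratio. Both margins are positive by construction (clusters/tissues with no
cells are dropped), so the expected table has no zeros. The identity
`Σ_j Ro/e_ij · (col_j/N) = 1` per cluster is property-tested. Display
banding of the figures' glyphs is left to the caller; values are written
with 3 decimals.

## Clustering glue (`ctxneu.cluster`)

`normalize_total → log1p → HVG (seurat flavor) → PCA → kNN graph → Leiden`
via scanpy/leidenalg, deterministic under the seed, parameters recorded in
the result. Constant-expression inputs short-circuit to a single cluster.
Resolution (default 0.8) is a display-granularity choice, not a tested
contract; on the default design the clustering recovers the five planted
expression states (three neutrophil tissue contexts, normal and malignant
epithelium) exactly, which is what the planted-truth ARI test asserts.

## Pipeline (`ctxneu.pipeline`)

One YAML config (versioned schema, unknown keys rejected) drives
simulate → qc → cluster → cnv → deg → scores → roe. Defaults are the
printed analysis parameters throughout: min_genes 250, max_mito 0.30, 2
doublet votes, window 100, cutoff 0.1, CNV threshold 0.04, fold change
1.2, p 0.001, top_n 21. All randomness flows from the single global seed
through named per-stage substreams (`SeedSequence(seed, spawn_key=(stage,))`),
so identical config + seed reproduces every output file byte for byte.
The two consensus detectors in the pipeline are two instances of the
native scorer with different neighbourhood sizes (k = 15 and 30) and
substream seeds; with external detectors available their calls would take
these slots. The CNV stage uses non-tumor epithelium as reference and
scores all epithelial cells; the report collects the QC funnel, the
malignancy confusion matrix against planted truth, the context sets with
their planted-program recovery, and the Ro/e table. Stage failures abort
with the stage named (CLI exit code 3; config errors exit 2), keeping
completed outputs.

## Problem sizes

The default demo design (3 patients × 3 tissues × 300 cells, 1,500 genes)
runs end-to-end in well under a minute on one CPU; the test suite and the
acceptance script use this scale or smaller (the bimod calibration uses
10,000 null genes at 50 cells per group, the Ro/e independence check
10,000 cells). These sizes were chosen to make every planted effect
comfortably recoverable while keeping a full run interactive.

## Known limitations

* The bimod χ²₃ reference is asymptotic; at very small group sizes the
  test drifts mildly anti-conservative (the calibration test bounds this
  at n = 50).
* The native doublet scorer cannot see same-type doublets (a limitation
  shared by all expression-based detectors); the consensus design assumes
  detectors err independently.
* The CNV score conflates genome-wide expression shifts with focal CNV;
  high-mito damaged cells must be removed first (QC does).
* The generator's shared NB dispersion and independent genes understate
  the correlation structure of real data; planted-truth recoveries here
  are upper bounds on real-data performance.
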