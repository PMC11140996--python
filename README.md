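# ctxneu

Context-dependent neutrophil-state analysis for multi-tissue single-cell
RNA-seq.

Tumor-associated neutrophils are not a single cell state: the same lineage
shows distinct transcriptional programs in blood, in non-malignant tissue,
and inside a tumor. In gallbladder cancer with liver invasion this
reprogramming tracks disease progression, and quantifying it requires a
handful of bespoke computations that sit on top of a standard scRNA-seq
pipeline. `ctxneu` implements those computations as a tested Python library
and CLI, together with a synthetic multi-tissue data generator so every
stage can be validated against planted ground truth without access to
patient-level data:

* **Cell QC with consensus doublet removal.** Cells with fewer than 250
  detected genes or more than 30% mitochondrial counts are excluded (strict
  inequalities). Doublets are removed only when flagged by at least two
  detectors; one simulation-based kNN scorer is built in, and calls from
  external tools plug into the same consensus interface.
* **Sliding-window CNV malignancy score.** Genes are sorted by genomic
  position; a 100-gene sliding window over reference-centred log expression
  yields CNVᵢ, the CNV estimate of window *i*. The per-cell score is
  mean(CNVᵢ²) over all windows, and cells with score > 0.04 are called
  malignant.
* **The bimod likelihood-ratio DEG test.** Log expression is modelled per
  gene as a point mass at zero plus a normal component on positive values;
  the LRT compares pooled vs per-group fits (χ², 3 df). A gene is
  significant when fold change > 1.2 **and** p < 0.001.
* **Context-dependent neutrophil scores.** Three gene sets built by
  intersecting directional DEG lists across blood / peritumor / tumor and
  keeping the top 21 genes: Nontumor-Activating (up outside the tumor),
  Tissue-Residing (up in tissue vs blood), Tumor-Modifying (up in tumor).
  Each per-cell score is the mean log-normalized expression over its set.
* **Ro/e tissue preference.** Observed over expected cell numbers in the
  cluster × tissue contingency table (expectation from the χ² independence
  model); Ro/e > 1 marks tissue enrichment.
* **Data-driven signatures.** KRT17-style construction: subtype DEGs
  unioned with genes positively correlated with an anchor gene, plus
  generic gene-set scoring for user-supplied signatures.

Clustering (HVG → PCA → kNN graph → Leiden) is deliberately delegated to
scanpy; `ctxneu` only records its parameters and consumes its labels.

## Worked example

Run the whole desk-scale workflow (simulate → QC → cluster → CNV → DEG →
context scores → Ro/e) from the bundled demo configuration:

```bash
ctxneu run --out demo --seed 7
```

This simulates 2,835 cells × 1,500 genes (3 patients × blood/peritumor/
tumor, neutrophils plus epithelium, one planted chromosome-scale gain in
malignant tumor cells, 5% doublets) and finishes in about half a minute.
`demo/report.json` then contains, among other things:

```text
qc funnel:   {'doublet': 40, 'high_mito': 133, 'pass': 2662}
cnv:         sensitivity 0.979, specificity 1.000   (tp 230, fp 0, fn 5, tn 648)
scores:      tumor_modifying  blood 1.41 < peritumor 1.95 < tumor 2.64
             nontumor_activating  blood 2.36 ≥ peritumor 2.33 > tumor 1.16
recovery:    all three 21-gene context sets ⊆ their planted programs (1.0)
```

Reading the numbers: the QC funnel reports why each cell was dropped; the
CNV block compares the 0.04-threshold malignancy calls against the planted
truth; the score block shows the blood → peritumor → tumor gradient of the
Tumor-Modifying score (and the reverse gradient of Nontumor-Activating)
that the method is designed to expose; recovery measures how much of each
planted tissue program the top-21 intersection sets found. `demo/roe.tsv`
holds the cluster × tissue Ro/e table, e.g. a tumor-restricted cluster
shows Ro/e ≈ 3 in tumor and 0 elsewhere.

Each stage is also a library function (`generate_dataset`,
`compute_cell_qc`, `infer_malignant`, `find_degs`, `build_context_scores`,
`build_signature`, `roe`, …) and a CLI subcommand (`ctxneu simulate`, `qc`,
`cluster`, `cnv`, `deg`, `scores`, `roe`) operating on a 10x-style MTX
triplet directory, so intermediates can be re-run individually.

## Documentation

`docs/methods.md` describes the statistical models, the synthetic-data
generator and its limits, all tunable parameters with defaults, and the
design decisions taken where conventions were open.
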