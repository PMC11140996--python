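"""Context-dependent neutrophil scores and gene-signature scoring.

Three per-cell activation scores summarise how neutrophil transcriptional
states depend on the tissue context (blood, peritumoral tissue, tumor). Each
score is the average log-normalized expression of a gene set built by
intersecting two directional DEG lists and keeping the top 21 genes:

* **Nontumor-Activating** — genes up in peritumor vs tumor that are also up
  in blood vs tumor (high outside the tumor), ranked by the peritumor-vs-
  tumor fold change;
* **Tissue-Residing** — genes up in peritumor vs blood that are also up in
  tumor vs blood (high in tissue regardless of malignancy), ranked by the
  peritumor-vs-blood fold change;
* **Tumor-Modifying** — genes up in tumor vs peritumor that are also up in
  tumor vs blood (tumor-specific), ranked by the tumor-vs-peritumor fold
  change.

The full significant DEG lists are intersected first and the intersection is
then truncated, so every retained gene satisfies both directional criteria.

The module also provides plain gene-set scoring (mean log-normalized
expression, optional z-scored variant) and data-driven signature
construction in the KRT17 style: subtype DEGs unioned with genes positively
correlated with an anchor gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ctxneu.dge import DegTable, find_degs
from ctxneu.preprocess import log_normalize

__all__ = [
    "ContextScoreSet",
    "Signature",
    "build_context_scores",
    "build_signature",
    "score_gene_set",
]

CONTEXT_CLASSES = ("blood", "peritumor", "tumor")
DEFAULT_TOP_N = 21


@dataclass
class ContextScoreSet:
    """The three context gene sets, their per-cell scores, and the DEG
    tables they were built from."""

    nontumor_activating: list[str]
    tissue_residing: list[str]
    tumor_modifying: list[str]
    scores: pd.DataFrame  # cells x 3 score columns
    provenance: dict[str, DegTable] = field(default_factory=dict)
    top_n: int = DEFAULT_TOP_N

    def gene_sets(self) -> dict[str, list[str]]:
        return {
            "nontumor_activating": list(self.nontumor_activating),
            "tissue_residing": list(self.tissue_residing),
            "tumor_modifying": list(self.tumor_modifying),
        }


@dataclass
class Signature:
    """A named gene set with its construction record."""

    name: str
    genes: list[str]
    construction: dict


def score_gene_set(
    adata: ad.AnnData, genes: Sequence[str], layer: str = "lognorm", zscore: bool = False
) -> np.ndarray:
    """Per-cell mean log-normalized expression over a gene set.

    Set genes missing from the matrix are dropped with a warning; if none
    remain this is an error. ``zscore=True`` standardises each gene across
    cells before averaging (module-score variant).
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ValueError("empty gene set")
    present = [g for g in genes if g in adata.var_names]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} gene(s) absent from matrix, dropped: {missing[:5]}")
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    log_normalize(adata, layer=layer)
    L = adata.layers[layer]
    sub = L[:, adata.var_names.get_indexer(present)]
    sub = sub.toarray() if sp.issparse(sub) else np.asarray(sub)
    if zscore:
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        sub = (sub - sub.mean(axis=0)) / sd
    return sub.mean(axis=1)


def _resolve_context(adata: ad.AnnData, tissue_label_map) -> np.ndarray:
    """Map per-cell tissue labels onto the three context classes."""
    if isinstance(tissue_label_map, str):
        raw = adata.obs[tissue_label_map].astype(str).to_numpy()
        mapping = {c: c for c in CONTEXT_CLASSES}
    elif isinstance(tissue_label_map, Mapping):
        raw = adata.obs["tissue"].astype(str).to_numpy()
        mapping = dict(tissue_label_map)
    else:
        raw = np.asarray(tissue_label_map, dtype=object)
        mapping = {c: c for c in CONTEXT_CLASSES}
    context = np.array([mapping.get(t, t) for t in raw], dtype=object)
    unknown = sorted(set(context) - set(CONTEXT_CLASSES))
    if unknown:
        raise ValueError(
            f"labels {unknown} do not map onto {CONTEXT_CLASSES}; extend the tissue map"
        )
    for c in CONTEXT_CLASSES:
        if not np.any(context == c):
            raise ValueError(f"context class {c!r} has no cells")
    return context


def build_context_scores(
    adata: ad.AnnData,
    tissue_label_map="tissue",
    top_n: int = DEFAULT_TOP_N,
    fc_threshold: float = 1.2,
    p_threshold: float = 0.001,
    test: str = "bimod",
) -> ContextScoreSet:
    """Build the three context-dependent scores on a neutrophil dataset.

    ``tissue_label_map`` is an ``obs`` column already holding the classes
    blood/peritumor/tumor, a mapping from raw tissue labels onto those
    classes (e.g. pooling adjacent liver and gallbladder into "peritumor"),
    or a per-cell array. An empty DEG intersection yields an empty set and
    an all-zero score, with a warning.
    """
    context = _resolve_context(adata, tissue_label_map)

    def degs(a: str, b: str) -> DegTable:
        return find_degs(
            adata, context, (a, b),
            fc_threshold=fc_threshold, p_threshold=p_threshold, test=test,
        )

    tables = {
        "peritumor_vs_tumor": degs("peritumor", "tumor"),
        "blood_vs_tumor": degs("blood", "tumor"),
        "peritumor_vs_blood": degs("peritumor", "blood"),
        "tumor_vs_blood": degs("tumor", "blood"),
        "tumor_vs_peritumor": degs("tumor", "peritumor"),
    }

    def intersect(primary: str, secondary: str, score_name: str) -> list[str]:
        ranked = tables[primary].significant_genes()
        other = set(tables[secondary].significant_genes())
        genes = [g for g in ranked if g in other][:top_n]
        if not genes:
            warnings.warn(f"{score_name}: empty DEG intersection; score set to 0")
        return genes

    nta = intersect("peritumor_vs_tumor", "blood_vs_tumor", "nontumor_activating")
    tr = intersect("peritumor_vs_blood", "tumor_vs_blood", "tissue_residing")
    tm = intersect("tumor_vs_peritumor", "tumor_vs_blood", "tumor_modifying")

    n = adata.n_obs
    scores = pd.DataFrame(
        {
            "nontumor_activating": score_gene_set(adata, nta) if nta else np.zeros(n),
            "tissue_residing": score_gene_set(adata, tr) if tr else np.zeros(n),
            "tumor_modifying": score_gene_set(adata, tm) if tm else np.zeros(n),
            "context": context,
        },
        index=adata.obs_names.copy(),
    )
    return ContextScoreSet(
        nontumor_activating=nta,
        tissue_residing=tr,
        tumor_modifying=tm,
        scores=scores,
        provenance=tables,
        top_n=top_n,
    )


def build_signature(
    adata: ad.AnnData,
    subtype_labels,
    anchor_gene: str,
    corr_threshold: float = 0.3,
    contrast: tuple[str, str] = ("LI", "Lo"),
    fc_threshold: float = 1.2,
    p_threshold: float = 0.001,
    name: str | None = None,
    layer: str = "lognorm",
) -> Signature:
    """Data-driven signature: subtype DEGs plus anchor-correlated genes.

    The gene set is the union of (i) genes significantly up in
    ``contrast[0]`` vs ``contrast[1]``, (ii) genes whose Pearson correlation
    with the anchor gene across all given cells exceeds ``corr_threshold``,
    and (iii) the anchor itself. A constant anchor leaves the correlation
    arm empty (with a warning) rather than failing.
    """
    if anchor_gene not in adata.var_names:
        raise ValueError(f"anchor gene {anchor_gene!r} absent from the matrix")
    deg_table = find_degs(
        adata, subtype_labels, contrast,
        fc_threshold=fc_threshold, p_threshold=p_threshold,
    )
    deg_genes = deg_table.significant_genes()

    log_normalize(adata, layer=layer)
    L = adata.layers[layer]
    L = L.toarray() if sp.issparse(L) else np.asarray(L)
    anchor = L[:, adata.var_names.get_loc(anchor_gene)]
    corr_genes: list[str] = []
    if np.std(anchor) == 0:
        warnings.warn(
            f"anchor gene {anchor_gene!r} is constant across cells; "
            "correlation arm contributes no genes"
        )
    else:
        centred = L - L.mean(axis=0)
        denom = np.linalg.norm(centred, axis=0) * np.linalg.norm(anchor - anchor.mean())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, centred.T @ (anchor - anchor.mean()) / denom, 0.0)
        order = np.argsort(-r, kind="stable")
        corr_genes = [
            adata.var_names[i] for i in order
            if r[i] > corr_threshold and adata.var_names[i] != anchor_gene
        ]
    genes = list(dict.fromkeys([anchor_gene, *deg_genes, *corr_genes]))
    return Signature(
        name=name or f"{anchor_gene}_signature",
        genes=genes,
        construction={
            "anchor_gene": anchor_gene,
            "corr_threshold": corr_threshold,
            "contrast": list(contrast),
            "n_deg_genes": len(deg_genes),
            "n_corr_genes": len(corr_genes),
            "fc_threshold": fc_threshold,
            "p_threshold": p_threshold,
        },
    )
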