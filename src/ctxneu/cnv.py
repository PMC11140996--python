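"""Expression-based CNV profiling and malignant-cell classification.

The procedure mirrors the windowed relative-expression approach used to
separate malignant from normal epithelial cells in tumor scRNA-seq:

1. drop genes whose mean normalized expression across all cells falls below
   a cutoff (default 0.1, on the median-library-size count scale), and all
   mitochondrial (chrM) genes;
2. log-normalize the retained genes (counts scaled to a fixed library size,
   ``log(1 + x)``), centre each gene on its mean over a set of reference
   normal cells, and clip to ``[-clip, +clip]`` (default 3);
3. sort genes by genomic position within each chromosome and slide a window
   of 100 genes (stride 1); ``CNVi``, the CNV estimate of window *i*, is the
   mean relative expression over the window's genes;
4. the per-cell CNV score is the mean of squared ``CNVi`` over all windows;
   cells whose score exceeds 0.04 (strictly) are called malignant.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ctxneu.preprocess import normalized_counts

__all__ = [
    "CnvProfile",
    "relative_expression",
    "sliding_windows",
    "cnv_profile",
    "cnv_score_and_call",
    "infer_malignant",
]

DEFAULT_WINDOW = 100
DEFAULT_CUTOFF = 0.1
DEFAULT_CLIP = 3.0
DEFAULT_THRESHOLD = 0.04


@dataclass
class CnvProfile:
    """Cell x window CNV profile with per-cell score and malignancy call."""

    windows: list[tuple[str, list[str]]]
    cnv_matrix: np.ndarray  # cells x windows
    cell_ids: pd.Index
    reference_cell_ids: frozenset
    cnv_score: np.ndarray | None = None
    is_malignant: np.ndarray | None = None
    threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.cnv_score is None:
            raise ValueError("scores not computed; call cnv_score_and_call first")
        return pd.DataFrame(
            {"cnv_score": self.cnv_score, "is_malignant": self.is_malignant},
            index=self.cell_ids,
        )


def relative_expression(
    adata: ad.AnnData,
    reference_cells,
    expression_cutoff: float = DEFAULT_CUTOFF,
    clip: float = DEFAULT_CLIP,
    target_sum: float = 1e4,
) -> tuple[np.ndarray, list[str]]:
    """Reference-centred, clipped log-normalized expression.

    Genes are screened on their mean expression across **all** cells after
    rescaling every cell to the median library size (so the cutoff reads on
    the raw-count scale); genes below ``expression_cutoff`` and chrM genes
    are removed. Retained genes are log-normalized to ``target_sum``, centred
    on the reference-cell mean and clipped to ``[-clip, clip]``.

    Returns ``(cells x genes dense matrix, retained gene ids)``.
    """
    reference_cells = pd.Index(reference_cells)
    if len(reference_cells) == 0:
        raise ValueError("reference cell set is empty")
    missing = reference_cells.difference(adata.obs_names)
    if len(missing):
        raise ValueError(f"reference cells absent from data: {list(missing[:3])}")

    keep = ~adata.var["is_mitochondrial"].to_numpy()
    mean_norm = np.asarray(normalized_counts(adata).mean(axis=0)).ravel()
    keep &= mean_norm >= expression_cutoff
    retained = adata.var_names[keep].tolist()
    if not retained:
        raise ValueError(f"no genes pass expression cutoff {expression_cutoff}")

    X = normalized_counts(adata, target_sum=target_sum).tocsc()[:, np.flatnonzero(keep)]
    logX = X.toarray()
    np.log1p(logX, out=logX)
    ref_idx = adata.obs_names.get_indexer(reference_cells)
    ref_mean = logX[ref_idx].mean(axis=0)
    rel = logX - ref_mean
    np.clip(rel, -clip, clip, out=rel)
    return rel, retained


def sliding_windows(
    gene_anno: pd.DataFrame, retained_genes, window_size: int = DEFAULT_WINDOW
) -> list[tuple[str, list[str]]]:
    """Stride-1 sliding windows of ``window_size`` genes along each
    chromosome, genes sorted by start position. A chromosome with fewer than
    ``window_size`` retained genes contributes one window holding them all;
    an empty chromosome contributes none."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    retained = pd.Index(retained_genes)
    anno = gene_anno.loc[retained]
    windows: list[tuple[str, list[str]]] = []
    for chrom in anno["chromosome"].unique():
        sub = anno[anno["chromosome"] == chrom]
        order = np.argsort(sub["start_position"].to_numpy(), kind="stable")
        genes = sub.index.to_numpy()[order]
        n = len(genes)
        if n == 0:
            continue
        if n < window_size:
            windows.append((chrom, list(genes)))
        else:
            for start in range(n - window_size + 1):
                windows.append((chrom, list(genes[start: start + window_size])))
    return windows


def cnv_profile(
    relative_matrix: np.ndarray,
    retained_genes,
    windows: list[tuple[str, list[str]]],
    cell_ids=None,
    reference_cell_ids=frozenset(),
) -> CnvProfile:
    """CNVi per (cell, window): the mean of the cell's relative expression
    over the window's genes."""
    retained = pd.Index(retained_genes)
    n_cells, n_genes = relative_matrix.shape
    if n_genes != len(retained):
        raise ValueError("relative_matrix width does not match retained gene list")
    # sparse gene -> window averaging operator
    rows, cols, vals = [], [], []
    for w, (_, genes) in enumerate(windows):
        idx = retained.get_indexer(genes)
        if np.any(idx < 0):
            bad = [g for g, i in zip(genes, idx) if i < 0]
            raise ValueError(f"window references genes not retained: {bad[:3]}")
        rows.extend(idx)
        cols.extend([w] * len(genes))
        vals.extend([1.0 / len(genes)] * len(genes))
    if not windows:
        raise ValueError("no windows supplied")
    W = sp.csr_matrix((vals, (rows, cols)), shape=(len(retained), len(windows)))
    cnv_matrix = np.asarray(relative_matrix @ W.todense())
    if cell_ids is None:
        cell_ids = pd.RangeIndex(n_cells)
    return CnvProfile(
        windows=windows,
        cnv_matrix=cnv_matrix,
        cell_ids=pd.Index(cell_ids),
        reference_cell_ids=frozenset(reference_cell_ids),
    )


def cnv_score_and_call(profile: CnvProfile, threshold: float = DEFAULT_THRESHOLD) -> CnvProfile:
    """Per-cell CNV score = mean of squared CNVi across all windows; a cell
    is malignant iff its score is strictly above ``threshold``."""
    if profile.cnv_matrix.shape[1] == 0:
        raise ValueError("profile has zero windows")
    score = np.mean(profile.cnv_matrix**2, axis=1)
    profile.cnv_score = score
    profile.is_malignant = score > threshold
    profile.threshold = threshold
    return profile


def infer_malignant(
    adata: ad.AnnData,
    reference_cells,
    window_size: int = DEFAULT_WINDOW,
    expression_cutoff: float = DEFAULT_CUTOFF,
    clip: float = DEFAULT_CLIP,
    threshold: float = DEFAULT_THRESHOLD,
) -> CnvProfile:
    """End-to-end CNV scoring: relative expression -> windows -> CNVi ->
    mean-of-squares score -> malignancy call."""
    rel, retained = relative_expression(
        adata, reference_cells, expression_cutoff=expression_cutoff, clip=clip
    )
    windows = sliding_windows(adata.var, retained, window_size=window_size)
    profile = cnv_profile(
        rel, retained, windows, cell_ids=adata.obs_names, reference_cell_ids=reference_cells
    )
    return cnv_score_and_call(profile, threshold=threshold)
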