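"""Cell-level quality control and consensus doublet removal.

Cells with fewer than 250 detected genes or more than 30% mitochondrial
counts are excluded (strict inequalities: a cell at exactly 250 genes or
exactly 30% mito passes). Doublets are removed by a consensus rule: a cell
is discarded only when at least two detectors flag it. One simulation-based
kNN detector is provided natively; calls from external tools can be fed into
the same consensus interface as scores or 0/1 votes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = ["QcReport", "compute_cell_qc", "score_doublets_simulated", "consensus_doublet_call"]

MIN_GENES = 250
MAX_MITO = 0.30


@dataclass
class QcReport:
    """Per-cell QC table: detected genes, mito fraction, doublet votes,
    pass/fail flag and the failure reason (low_genes / high_mito / doublet /
    pass)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        expected = (self.table["reason"] == "pass") == self.table["pass_filters"]
        if not expected.all():
            raise ValueError("pass_filters must be true exactly when reason == 'pass'")

    @property
    def n_pass(self) -> int:
        return int(self.table["pass_filters"].sum())

    @property
    def n_fail(self) -> int:
        return int((~self.table["pass_filters"]).sum())

    def passing_cells(self) -> pd.Index:
        return self.table.index[self.table["pass_filters"]]


def compute_cell_qc(
    adata: ad.AnnData, min_genes: int = MIN_GENES, max_mito: float = MAX_MITO
) -> QcReport:
    """Gene-count and mitochondrial filters on raw counts.

    ``mito_fraction`` is the fraction of a cell's counts on mitochondrial
    genes (computed before any normalization). Cells with zero total counts
    fail as ``low_genes``. Doublet columns are left unset (votes = -1).
    """
    if "is_mitochondrial" not in adata.var.columns:
        raise ValueError("gene annotation lacks 'is_mitochondrial'")
    X = sp.csr_matrix(adata.X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_mask = adata.var["is_mitochondrial"].to_numpy()
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel().astype(float)
    mito_fraction = np.divide(mito, total, out=np.zeros_like(mito), where=total > 0)

    reason = np.full(adata.n_obs, "pass", dtype=object)
    reason[mito_fraction > max_mito] = "high_mito"
    reason[n_genes < min_genes] = "low_genes"  # low_genes takes precedence
    table = pd.DataFrame(
        {
            "n_genes_detected": n_genes.astype(int),
            "mito_fraction": mito_fraction,
            "doublet_votes": -1,
            "pass_filters": reason == "pass",
            "reason": reason,
        },
        index=adata.obs_names.copy(),
    )
    return QcReport(table)


def score_doublets_simulated(
    adata: ad.AnnData,
    n_simulated: int | None = None,
    k_neighbors: int = 20,
    seed: int = 0,
    n_pcs: int = 30,
    sample_key: str | None = None,
) -> np.ndarray:
    """Simulation-based kNN doublet score in [0, 1].

    Synthetic doublets are built as barcode collisions arise: the counts of
    two randomly chosen cells of the same sample are summed (library-size
    normalization of the pool absorbs the doubled depth, so no downsampling
    is applied). Observed cells and synthetic doublets are pooled,
    log-normalized, embedded by PCA, and each observed cell is scored by the
    fraction of its ``k_neighbors`` nearest pooled neighbours (self
    excluded) that are synthetic. The default simulates one doublet per four
    observed cells, keeping same-type ("embedded") synthetic doublets from
    inflating singlet scores.
    """
    n = adata.n_obs
    if n_simulated is None:
        n_simulated = max(n // 4, 2)
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    if n < 2 * k_neighbors:
        raise ValueError("need at least 2*k_neighbors cells")
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(adata.X).astype(np.int64)

    if sample_key is not None:
        groups = adata.obs[sample_key].to_numpy()
    else:
        groups = np.zeros(n, dtype=int)
    group_index = {g: np.flatnonzero(groups == g) for g in pd.unique(groups)}
    eligible = [g for g, idx in group_index.items() if len(idx) >= 2]
    if not eligible:
        raise ValueError("no sample with >= 2 cells to draw doublets from")

    sim_rows = []
    weights = np.array([len(group_index[g]) for g in eligible], dtype=float)
    weights /= weights.sum()
    for _ in range(n_simulated):
        g = eligible[rng.choice(len(eligible), p=weights)]
        a, b = rng.choice(group_index[g], size=2, replace=False)
        sim_rows.append(X[a] + X[b])
    pooled = sp.vstack([X.astype(float)] + sim_rows, format="csr")

    # log-normalize the pool and embed
    libs = np.asarray(pooled.sum(axis=1)).ravel()
    scale = np.divide(1e4, libs, out=np.zeros_like(libs, dtype=float), where=libs > 0)
    pooled = sp.diags(scale) @ pooled
    pooled.data = np.log1p(pooled.data)
    n_comp = min(n_pcs, pooled.shape[0] - 1, pooled.shape[1] - 1)
    emb = PCA(n_components=max(n_comp, 1), random_state=int(seed) % (2**31)).fit_transform(
        np.asarray(pooled.todense())
    )
    # infinitesimal jitter so exact ties (degenerate identical cells) break
    # randomly instead of by index order
    emb = emb + rng.normal(scale=1e-9 * max(emb.std(), 1.0), size=emb.shape)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neighbor_is_sim = idx[:, 1:] >= n  # drop self (column 0)
    return neighbor_is_sim.mean(axis=1)


def consensus_doublet_call(
    scores: Sequence[np.ndarray],
    thresholds: Sequence[float] | float = 0.5,
    min_votes: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Consensus over detectors: flag a cell iff at least ``min_votes``
    detectors call it (score_i >= threshold_i). Pre-thresholded 0/1 calls can
    be passed with threshold 0.5.

    Returns ``(is_doublet, votes)``.
    """
    if len(scores) < 2:
        raise ValueError("consensus requires at least two detectors")
    arrays = [np.asarray(s, dtype=float) for s in scores]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"detector score vectors have mismatched lengths: {sorted(lengths)}")
    if np.isscalar(thresholds):
        thresholds = [float(thresholds)] * len(arrays)
    if len(thresholds) != len(arrays):
        raise ValueError("need one threshold per detector")
    votes = np.sum([a >= t for a, t in zip(arrays, thresholds)], axis=0).astype(int)
    return votes >= min_votes, votes


def apply_qc(
    report: QcReport, doublet_flags: np.ndarray | None = None, votes: np.ndarray | None = None
) -> QcReport:
    """Fold consensus doublet calls into a QC report. Doublet failure applies
    to cells that would otherwise pass (the two filters commute: both are
    functions of the raw counts alone)."""
    table = report.table.copy()
    if doublet_flags is not None:
        doublet_flags = np.asarray(doublet_flags, dtype=bool)
        if doublet_flags.shape[0] != len(table):
            raise ValueError("doublet flag length does not match report")
        table.loc[doublet_flags & (table["reason"] == "pass"), "reason"] = "doublet"
        table["pass_filters"] = table["reason"] == "pass"
    if votes is not None:
        table["doublet_votes"] = np.asarray(votes, dtype=int)
    return QcReport(table)
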