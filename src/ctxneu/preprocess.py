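"""Library-size normalization helpers shared by the analysis stages."""

from __future__ import annotations

import anndata as ad
import numpy as np
import scipy.sparse as sp

__all__ = ["log_normalize", "normalized_counts"]


def _library_scale(X, target_sum: float) -> np.ndarray:
    lib = np.asarray(X.sum(axis=1)).ravel()
    scale = np.zeros_like(lib, dtype=float)
    nz = lib > 0
    scale[nz] = target_sum / lib[nz]
    return scale


def normalized_counts(adata: ad.AnnData, target_sum: float | None = None) -> sp.csr_matrix:
    """Counts rescaled so every cell sums to ``target_sum`` (default: the
    median library size, keeping values on the raw-count scale). Zero-count
    cells stay zero."""
    X = sp.csr_matrix(adata.X, dtype=float)
    if target_sum is None:
        lib = np.asarray(X.sum(axis=1)).ravel()
        target_sum = float(np.median(lib[lib > 0])) if np.any(lib > 0) else 1.0
    scale = _library_scale(X, target_sum)
    return sp.diags(scale) @ X


def log_normalize(
    adata: ad.AnnData, target_sum: float = 1e4, layer: str = "lognorm"
) -> ad.AnnData:
    """Standard log-normalization: counts scaled to ``target_sum`` per cell,
    then ``log(1 + x)``; stored in ``adata.layers[layer]``. Returns ``adata``
    for chaining; no-op if the layer already exists."""
    if layer in adata.layers:
        return adata
    X = normalized_counts(adata, target_sum=target_sum)
    X.data = np.log1p(X.data)
    adata.layers[layer] = X.tocsr()
    return adata
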