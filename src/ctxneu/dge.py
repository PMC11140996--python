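"""Two-group differential expression with the bimodal likelihood-ratio test.

Log-normalized single-cell expression is modelled per gene as a mixture of a
point mass at zero (dropout) and a normal component on the positive values:

    x = 0            with probability 1 - alpha
    x ~ N(mu, sigma) with probability alpha,  x > 0

The likelihood-ratio statistic compares one mixture fitted to the pooled
cells against separate mixtures per group,

    LRT = 2 * (l_A + l_B - l_pooled),

and is referred to a chi-square with 3 degrees of freedom (alpha, mu, sigma
each freed). All three maximum-likelihood estimates are closed form: alpha is
the detection fraction (clamped to [1e-5, 1 - 1e-5]), mu and sigma^2 the
mean and 1/n variance of the positive values, with a variance floor of 1e-6
for degenerate groups.

A gene is called significant when the fold change exceeds ``fc_threshold``
(default 1.2) AND the raw p-value falls below ``p_threshold`` (default
0.001). The fold change is the ratio of ``mean(expm1(logexpr))`` between the
groups (plus 1e-9 in numerator and denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ctxneu.preprocess import log_normalize

__all__ = ["DegTable", "bimod_lrt", "find_degs"]

_ALPHA_CLAMP = 1e-5
_VAR_FLOOR = 1e-6
_FC_EPS = 1e-9
_DF = 3


@dataclass
class DegTable:
    """Per-gene results of one two-group contrast (A vs B).

    ``frame`` columns: log2_fc, fold_change, pct_a, pct_b, lrt_stat,
    p_value, p_adj (Benjamini-Hochberg, informational only — the
    significance gate uses the raw p as stated), significant.
    """

    frame: pd.DataFrame
    contrast: tuple[str, str]
    fc_threshold: float
    p_threshold: float
    test: str

    def significant_genes(self) -> list[str]:
        """Genes up in A vs B passing both gates, in table (ranked) order."""
        return self.frame.index[self.frame["significant"]].tolist()


def _mixture_loglik(n_zero, n_pos, sum_pos, sumsq_pos):
    """Maximized bimodal log-likelihood, vectorized over genes."""
    n_zero = np.asarray(n_zero, dtype=float)
    n_pos = np.asarray(n_pos, dtype=float)
    n = n_zero + n_pos
    alpha = np.clip(n_pos / n, _ALPHA_CLAMP, 1.0 - _ALPHA_CLAMP)
    ll = n_zero * np.log1p(-alpha) + n_pos * np.log(alpha)

    has_pos = n_pos > 0
    mu = np.divide(sum_pos, n_pos, out=np.zeros_like(alpha), where=has_pos)
    msq = np.divide(sumsq_pos, n_pos, out=np.zeros_like(alpha), where=has_pos)
    var_mle = np.maximum(msq - mu**2, 0.0)
    var = np.maximum(var_mle, _VAR_FLOOR)
    norm_ll = -0.5 * n_pos * (np.log(2.0 * np.pi * var) + var_mle / var)
    return ll + np.where(has_pos, norm_ll, 0.0)


def _bimod_lrt_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LRT statistic and p-value per gene for dense (cells x genes) groups."""
    def suff(M):
        pos = M > 0
        n_pos = pos.sum(axis=0)
        return (
            M.shape[0] - n_pos,
            n_pos,
            np.where(pos, M, 0.0).sum(axis=0),
            np.where(pos, M**2, 0.0).sum(axis=0),
        )

    sA, sB = suff(A), suff(B)
    pooled = tuple(a + b for a, b in zip(sA, sB))
    stat = 2.0 * (_mixture_loglik(*sA) + _mixture_loglik(*sB) - _mixture_loglik(*pooled))
    stat = np.maximum(stat, 0.0)  # exact MLEs guarantee >= 0 up to rounding
    p = stats.chi2.sf(stat, _DF)
    return stat, np.clip(p, np.finfo(float).tiny, 1.0)


def bimod_lrt(x, y) -> tuple[float, float]:
    """Bimodal LRT for two log-expression vectors; returns (stat, p_value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("x and y must be 1-D expression vectors")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 cells")
    stat, p = _bimod_lrt_matrix(x[:, None], y[:, None])
    return float(stat[0]), float(p[0])


def find_degs(
    adata: ad.AnnData,
    group_labels,
    contrast: tuple[str, str],
    fc_threshold: float = 1.2,
    p_threshold: float = 0.001,
    test: str = "bimod",
    rank_by: str = "fc",
    layer: str = "lognorm",
) -> DegTable:
    """Per-gene two-group test on log-normalized expression.

    ``group_labels`` is an ``obs`` column name or a per-cell array;
    ``contrast=(A, B)`` tests A against B, with positive log2_fc meaning
    higher in A. The table is sorted by descending fold change then
    ascending p (``rank_by="p"`` swaps the keys).
    """
    if test not in ("bimod", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    if rank_by not in ("fc", "p"):
        raise ValueError(f"unknown ranking {rank_by!r}")
    labels = (
        adata.obs[group_labels].to_numpy()
        if isinstance(group_labels, str)
        else np.asarray(group_labels)
    )
    if labels.shape[0] != adata.n_obs:
        raise ValueError("group labels do not match cell count")
    a_name, b_name = contrast
    mask_a = labels == a_name
    mask_b = labels == b_name
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError(
            f"contrast needs >= 3 cells per group (got {int(mask_a.sum())} {a_name!r}, "
            f"{int(mask_b.sum())} {b_name!r})"
        )
    log_normalize(adata, layer=layer)
    L = adata.layers[layer]
    L = L.toarray() if sp.issparse(L) else np.asarray(L)
    A = L[mask_a]
    B = L[mask_b]

    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    fold_change = (mean_a + _FC_EPS) / (mean_b + _FC_EPS)
    log2_fc = np.log2(fold_change)
    pct_a = (A > 0).mean(axis=0)
    pct_b = (B > 0).mean(axis=0)

    if test == "bimod":
        stat, p = _bimod_lrt_matrix(A, B)
    else:
        res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided", method="asymptotic")
        stat, p = res.statistic, np.clip(res.pvalue, np.finfo(float).tiny, 1.0)

    frame = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "fold_change": fold_change,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "lrt_stat": stat,
            "p_value": p,
            "p_adj": stats.false_discovery_control(p, method="bh"),
            "significant": (fold_change > fc_threshold) & (p < p_threshold),
        },
        index=adata.var_names.copy(),
    )
    if rank_by == "fc":
        frame = frame.sort_values(["fold_change", "p_value"], ascending=[False, True], kind="stable")
    else:
        frame = frame.sort_values(["p_value", "fold_change"], ascending=[True, False], kind="stable")
    return DegTable(
        frame=frame,
        contrast=(a_name, b_name),
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        test=test,
    )
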