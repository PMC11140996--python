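"""Tissue preference of cell clusters by the Ro/e statistic.

Ro/e is the elementwise ratio of the observed cluster x tissue contingency
table to the expected counts under the chi-square independence model
(expected_ij = row_i * col_j / N). A value above 1 means the cluster is
enriched in that tissue, below 1 depleted; 0 means absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats.contingency import expected_freq

__all__ = ["RoeMatrix", "roe"]


@dataclass
class RoeMatrix:
    """Observed, expected, and Ro/e cluster x tissue tables."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    ratio: pd.DataFrame

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        return self.ratio.round(decimals)


def roe(cluster_labels, tissue_labels) -> RoeMatrix:
    """Ro/e for per-cell cluster and tissue label vectors.

    Requires at least one cell per tissue column; clusters with zero cells
    (unused categorical levels) are dropped.
    """
    clusters = pd.Series(np.asarray(cluster_labels, dtype=object), name="cluster")
    tissues = pd.Series(np.asarray(tissue_labels, dtype=object), name="tissue")
    if len(clusters) != len(tissues):
        raise ValueError("cluster and tissue label vectors differ in length")
    if len(clusters) == 0:
        raise ValueError("empty input")
    observed = pd.crosstab(clusters, tissues)
    observed = observed.loc[observed.sum(axis=1) > 0, observed.sum(axis=0) > 0]
    expected = pd.DataFrame(
        expected_freq(observed.to_numpy()), index=observed.index, columns=observed.columns
    )
    ratio = observed / expected
    return RoeMatrix(observed=observed, expected=expected, ratio=ratio)
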