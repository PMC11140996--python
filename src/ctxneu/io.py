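"""Disk layout: 10x-style Matrix Market triplet plus TSV metadata.

A dataset directory holds ``matrix.mtx`` (genes x cells, coordinate integer),
``features.tsv`` / ``barcodes.tsv`` and the two metadata tables
``cell_meta.tsv`` / ``gene_anno.tsv``; the generating design, when known, is
saved as ``design.yaml``. ``read_dataset(write_dataset(x))`` round-trips
counts and metadata exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from ctxneu.simulate import GENE_ANNO_COLUMNS, validate_count_matrix

__all__ = ["write_dataset", "read_dataset"]

_FILES = ("matrix.mtx", "features.tsv", "barcodes.tsv", "cell_meta.tsv", "gene_anno.tsv")


def write_dataset(adata: ad.AnnData, directory: str | os.PathLike, overwrite: bool = False) -> Path:
    """Write a count dataset as a 10x-style MTX triplet with TSV metadata.

    Refuses to clobber an existing dataset unless ``overwrite`` is set.
    """
    validate_count_matrix(adata)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    existing = [f for f in _FILES if (directory / f).exists()]
    if existing and not overwrite:
        raise FileExistsError(
            f"{directory} already holds {existing}; pass overwrite=True to replace"
        )

    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    genes_by_cells = sp.coo_matrix(X.T).astype(np.int64)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), genes_by_cells, field="integer")

    features = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    features.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)

    adata.obs.to_csv(directory / "cell_meta.tsv", sep="\t", index=True, index_label="cell_id")
    adata.var.to_csv(directory / "gene_anno.tsv", sep="\t", index=True, index_label="gene_id")

    if "design" in adata.uns:
        with open(directory / "design.yaml", "w") as fh:
            yaml.safe_dump(adata.uns["design"], fh, sort_keys=False)
    return directory


def _parse_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.map({"True": True, "False": False, True: True, False: False}).astype(bool)


def read_dataset(directory: str | os.PathLike) -> ad.AnnData:
    """Inverse of :func:`write_dataset`."""
    directory = Path(directory)
    for f in _FILES:
        if not (directory / f).exists():
            raise FileNotFoundError(f"{directory / f} missing; not a dataset directory")

    genes_by_cells = scipy.io.mmread(str(directory / "matrix.mtx"))
    X = sp.csr_matrix(genes_by_cells.T).astype(np.int64)

    obs = pd.read_csv(directory / "cell_meta.tsv", sep="\t", index_col="cell_id", dtype={0: str})
    obs.index = obs.index.astype(str)
    for col in ("true_is_malignant", "true_is_doublet"):
        if col in obs.columns:
            obs[col] = _parse_bool(obs[col])
    var = pd.read_csv(directory / "gene_anno.tsv", sep="\t", index_col="gene_id")
    var.index = var.index.astype(str)
    var["is_mitochondrial"] = _parse_bool(var["is_mitochondrial"])
    var["start_position"] = var["start_position"].astype(np.int64)

    missing = [c for c in GENE_ANNO_COLUMNS if c not in var.columns]
    if missing:
        raise ValueError(f"gene_anno.tsv lacks columns {missing}")
    adata = ad.AnnData(X=X, obs=obs, var=var)
    design_file = directory / "design.yaml"
    if design_file.exists():
        with open(design_file) as fh:
            adata.uns["design"] = yaml.safe_load(fh)
    validate_count_matrix(adata)
    return adata
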