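"""Reading and writing datasets as MTX + TSV sidecars.

On disk a dataset is ``matrix.mtx`` (genes x cells, MatrixMarket integer
sparse), ``cells.tsv`` (cell_id, sample, phenotype, subtype, mito_frac) and
``genes.tsv`` (gene metadata indexed by gene id). Ground truth, when present,
is ``ground_truth.tsv`` (gene-role table) plus ``ground_truth_hd_lfc.tsv``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .syndata import GroundTruth

REQUIRED_CELL_COLUMNS = ("sample", "phenotype", "subtype")


def write_dataset(adata: ad.AnnData, outdir: str | Path,
                  ground_truth: GroundTruth | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scio.mmwrite(str(outdir / "matrix.mtx"), X.T.astype(np.int64))
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t", index_label="cell_id")
    adata.var.to_csv(outdir / "genes.tsv", sep="\t", index_label="gene")
    if ground_truth is not None:
        gt = ground_truth.genes.copy()
        gt["directionality"] = ground_truth.directionality
        gt.to_csv(outdir / "ground_truth.tsv", sep="\t", index_label="gene")
        ground_truth.hd_lfc.to_csv(outdir / "ground_truth_hd_lfc.tsv", sep="\t",
                                   index_label="gene")
        ground_truth.depletion.to_frame().to_csv(
            outdir / "ground_truth_depletion.tsv", sep="\t",
            index_label="subtype")
    return outdir


def read_dataset(mtx: str | Path, cells_tsv: str | Path,
                 genes_tsv: str | Path) -> ad.AnnData:
    """Load a genes x cells MTX with its cell/gene TSV sidecars into AnnData."""
    X = sparse.csr_matrix(scio.mmread(str(mtx)).T)
    obs = pd.read_csv(cells_tsv, sep="\t", index_col=0)
    var = pd.read_csv(genes_tsv, sep="\t", index_col=0)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"cells.tsv missing required columns: {missing}")
    if X.shape != (len(obs), len(var)):
        raise ValueError(
            f"matrix shape {X.shape} does not match cells x genes "
            f"({len(obs)} x {len(var)})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ad.AnnData(X=X, obs=obs, var=var)


def load_dataset_dir(path: str | Path) -> ad.AnnData:
    path = Path(path)
    return read_dataset(path / "matrix.mtx", path / "cells.tsv",
                        path / "genes.tsv")
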