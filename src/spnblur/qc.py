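"""Cell-level quality control.

Cells are removed when their mitochondrial read fraction is strictly above
the species threshold (5% mouse, 20% human) or when they express fewer than
a global minimum number of unique genes (default 500, boundary retained). An
optional MAD-based rule removes cells whose total RNA content is extreme
relative to their own subtype's distribution; it stands in for unspecified
cluster-relative bounds and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

SPECIES_MITO_MAX = {"mouse": 0.05, "human": 0.20}


@dataclass(frozen=True)
class QcThresholds:
    species: str = "mouse"
    max_mito_frac: float | None = None  # None -> species default
    min_unique_genes: int = 500
    mad_rule: bool = False
    mad_k: float = 5.0

    def resolved_max_mito(self) -> float:
        if self.max_mito_frac is not None:
            v = self.max_mito_frac
        else:
            if self.species not in SPECIES_MITO_MAX:
                raise ValueError(f"unknown species {self.species!r}")
            v = SPECIES_MITO_MAX[self.species]
        if not 0.0 <= v <= 1.0:
            raise ValueError("max_mito_frac must be in [0, 1]")
        return v

    def validate(self) -> None:
        self.resolved_max_mito()
        if self.min_unique_genes < 0:
            raise ValueError("min_unique_genes must be >= 0")


@dataclass
class QcReport:
    """Removal counts per reason, per sample."""

    n_input: int
    n_retained: int
    per_sample: pd.DataFrame  # columns: input, mito, low_genes, mad, retained
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": int(self.n_input),
            "n_retained": int(self.n_retained),
            "thresholds": self.thresholds,
            "per_sample": {s: {k: int(v) for k, v in row.items()}
                           for s, row in self.per_sample.iterrows()},
        }


def _mito_fraction(adata: ad.AnnData) -> np.ndarray:
    if "is_mito" not in adata.var.columns:
        raise ValueError("gene metadata lacks an 'is_mito' flag column")
    mito = adata.var["is_mito"].to_numpy().astype(bool)
    if not mito.any():
        raise ValueError("no genes flagged mitochondrial; "
                         "cannot compute mito fraction")
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    mt = np.asarray(X[:, mito].sum(axis=1)).ravel()
    return mt / np.maximum(total, 1)


def filter_cells(adata: ad.AnnData,
                 thresholds: QcThresholds) -> tuple[ad.AnnData, QcReport]:
    """Apply the QC thresholds; returns the filtered matrix and a report.

    Removal reasons are assessed on the input matrix (a cell failing both
    rules is counted under the mito reason first). The gene set is unchanged.
    Raises if every cell would be removed.
    """
    thresholds.validate()
    max_mito = thresholds.resolved_max_mito()
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    mito_frac = _mito_fraction(adata)
    unique_genes = np.asarray((X > 0).sum(axis=1)).ravel()

    fail_mito = mito_frac > max_mito
    fail_genes = unique_genes < thresholds.min_unique_genes
    fail_mad = np.zeros(adata.n_obs, dtype=bool)
    if thresholds.mad_rule:
        total = np.log1p(np.asarray(X.sum(axis=1)).ravel())
        for t in adata.obs["subtype"].unique():
            sel = (adata.obs["subtype"] == t).to_numpy()
            med = np.median(total[sel])
            mad = np.median(np.abs(total[sel] - med))
            if mad > 0:
                fail_mad[sel] = np.abs(total[sel] - med) > thresholds.mad_k * mad

    keep = ~(fail_mito | fail_genes | fail_mad)
    if not keep.any():
        raise ValueError("QC removed every cell; thresholds leave an empty "
                         "matrix")

    reason = pd.DataFrame({
        "sample": adata.obs["sample"].to_numpy(),
        "mito": fail_mito,
        "low_genes": fail_genes & ~fail_mito,
        "mad": fail_mad & ~fail_mito & ~fail_genes,
        "retained": keep,
    })
    per_sample = reason.groupby("sample", sort=True).agg(
        input=("retained", "size"), mito=("mito", "sum"),
        low_genes=("low_genes", "sum"), mad=("mad", "sum"),
        retained=("retained", "sum"))
    report = QcReport(
        n_input=adata.n_obs, n_retained=int(keep.sum()), per_sample=per_sample,
        thresholds={"species": thresholds.species, "max_mito_frac": max_mito,
                    "min_unique_genes": thresholds.min_unique_genes,
                    "mad_rule": thresholds.mad_rule})
    out = adata[keep].copy()
    out.obs["mito_frac"] = mito_frac[keep]
    return out, report
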