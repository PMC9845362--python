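"""Pseudobulk differential expression.

Counts are summed per (sample, subtype) group, normalized to log2 CPM with a
prior count, and tested per gene with (optionally weighted) least squares on
a design matrix; significance calls use an absolute log2FC floor and an
FDR-adjusted p ceiling. A bootstrap over samples and cells quantifies the
robustness of each gene's call to cell-type abundance.

The weighted mode implements "gene-wise single-cell-level variance as
weights": per (gene, group) weight = n_cells / (within-group single-cell
variance + floor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PRIOR = 1.0
DEFAULT_VAR_FLOOR = 0.5
_ZERO_VAR_TOL = 1e-12

DGE_COLUMNS = ("log2fc", "se", "t", "pvalue", "padj", "mean_log2cpm",
               "n_group1", "n_group2")


@dataclass
class PseudobulkTable:
    """Per-(sample, subtype) aggregated counts.

    counts : genes x groups summed counts (exact column sums of member cells).
    log2cpm : log2(1e6 * count / library + prior).
    meta : per group — sample, subtype, phenotype, n_cells, lib_size.
    cell_var : genes x groups within-group variance of per-cell counts
        (ddof=0), used by the inverse-variance weighting mode.
    Groups with zero cells are absent, never zero-filled.
    """

    counts: pd.DataFrame
    log2cpm: pd.DataFrame
    meta: pd.DataFrame
    cell_var: pd.DataFrame
    prior: float = DEFAULT_PRIOR

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def rows(self, subtype: str | None = None,
             phenotype: str | None = None) -> pd.Index:
        sel = pd.Series(True, index=self.meta.index)
        if subtype is not None:
            sel &= self.meta["subtype"] == subtype
        if phenotype is not None:
            sel &= self.meta["phenotype"] == phenotype
        return self.meta.index[sel]


def aggregate_pseudobulk(adata: ad.AnnData,
                         prior: float = DEFAULT_PRIOR) -> PseudobulkTable:
    """Sum counts per (sample, subtype) and normalize to log2 CPM."""
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    X = X.tocsr()
    obs = adata.obs
    groups = obs.groupby(["sample", "subtype"], observed=True, sort=True)
    cols, sums, vars, meta_rows = [], [], [], []
    for (s, t), idx in groups.indices.items():
        sub = X[idx]
        total = np.asarray(sub.sum(axis=0)).ravel()
        if total.sum() == 0:
            raise ValueError(f"group ({s}, {t}) has zero total library size")
        mean = total / len(idx)
        sq = np.asarray(sub.multiply(sub).sum(axis=0)).ravel() / len(idx)
        phen = obs["phenotype"].iloc[idx]
        if phen.nunique() != 1:
            raise ValueError(f"sample {s!r} maps to multiple phenotypes")
        cols.append(f"{s}|{t}")
        sums.append(total)
        vars.append(sq - mean ** 2)
        meta_rows.append((s, t, phen.iloc[0], len(idx), float(total.sum())))
    counts = pd.DataFrame(np.column_stack(sums), index=adata.var_names,
                          columns=cols)
    cell_var = pd.DataFrame(np.column_stack(vars), index=adata.var_names,
                            columns=cols)
    meta = pd.DataFrame(meta_rows, index=cols,
                        columns=["sample", "subtype", "phenotype", "n_cells",
                                 "lib_size"])
    log2cpm = np.log2(1e6 * counts / meta["lib_size"].to_numpy() + prior)
    return PseudobulkTable(counts=counts, log2cpm=log2cpm, meta=meta,
                           cell_var=cell_var, prior=prior)


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _check_design(X: np.ndarray, columns: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        redundant = [c for j, c in enumerate(columns)
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"design matrix is rank-deficient; collinear "
                         f"columns: {redundant}")


def fit_dge(pb: PseudobulkTable, design: pd.DataFrame, contrast: str,
            weights_mode: str = "none",
            var_floor: float = DEFAULT_VAR_FLOOR) -> pd.DataFrame:
    """Per-gene least squares of log2CPM on a design matrix.

    ``design`` is indexed by pseudobulk group ids and must contain the
    ``contrast`` column; an intercept column of ones is added when absent.
    The reported log2FC is the contrast coefficient, with a two-sided t test
    on the residual degrees of freedom and BH adjustment across genes.
    Genes with (numerically) zero residual variance get p = 1, t = 0.
    """
    if contrast not in design.columns:
        raise ValueError(f"contrast column {contrast!r} not in design")
    missing = design.index.difference(pb.meta.index)
    if len(missing):
        raise ValueError(f"design rows not in pseudobulk table: {list(missing)}")
    design = design.astype(float)
    if "const" not in design.columns:
        design = design.assign(const=1.0)
    X = design.to_numpy()
    _check_design(X, list(design.columns))
    R, k = X.shape
    df = R - k
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")

    Y = pb.log2cpm[design.index].to_numpy()  # G x R
    ci = list(design.columns).index(contrast)

    if weights_mode == "none":
        pinv = np.linalg.pinv(X)  # k x R
        beta = Y @ pinv.T  # G x k
        resid = Y - beta @ X.T
        rss = np.einsum("gr,gr->g", resid, resid)
        s2 = rss / df
        xtx_inv_cc = np.linalg.inv(X.T @ X)[ci, ci]
        var_c = s2 * xtx_inv_cc
    elif weights_mode == "inverse_cell_variance":
        W = (pb.meta.loc[design.index, "n_cells"].to_numpy()[None, :]
             / (pb.cell_var[design.index].to_numpy() + var_floor))  # G x R
        XtWX = np.einsum("ri,gr,rj->gij", X, W, X)
        XtWY = np.einsum("ri,gr,gr->gi", X, W, Y)
        beta = np.linalg.solve(XtWX, XtWY[..., None])[..., 0]  # G x k
        resid = Y - beta @ X.T
        rss = np.einsum("gr,gr,gr->g", resid, W, resid)
        s2 = rss / df
        var_c = s2 * np.linalg.inv(XtWX)[:, ci, ci]
    else:
        raise ValueError(f"unknown weights_mode {weights_mode!r}")

    lfc = beta[:, ci]
    lfc[np.abs(lfc) < 1e-12] = 0.0
    zero = s2 < _ZERO_VAR_TOL
    se = np.sqrt(np.maximum(var_c, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero | (se == 0), 0.0, lfc / np.where(se == 0, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, 1.0, p)

    xc = X[:, ci]
    n1 = int((xc != 0).sum())
    n2 = R - n1
    out = pd.DataFrame(
        {"log2fc": lfc, "se": se, "t": t, "pvalue": p,
         "padj": bh_adjust(p), "mean_log2cpm": Y.mean(axis=1),
         "n_group1": n1, "n_group2": n2},
        index=pb.genes)
    out.attrs["contrast"] = contrast
    out.attrs["df"] = df
    return out


def _two_group_design(rows_alt: pd.Index, rows_ref: pd.Index,
                      name: str) -> pd.DataFrame:
    idx = rows_alt.append(rows_ref)
    return pd.DataFrame({name: [1.0] * len(rows_alt) + [0.0] * len(rows_ref)},
                        index=idx)


def dge_hd_vs_control(pb: PseudobulkTable, subtype: str,
                      weights_mode: str = "none", **kw) -> pd.DataFrame:
    """Disease-vs-control contrast within one subtype (positive = up in HD)."""
    alt = pb.rows(subtype=subtype, phenotype="HD")
    ref = pb.rows(subtype=subtype, phenotype="control")
    if len(alt) < 2 or len(ref) < 2:
        raise ValueError(f"need >= 2 samples per phenotype for {subtype!r}")
    design = _two_group_design(alt, ref, "HD")
    return fit_dge(pb, design, "HD", weights_mode=weights_mode, **kw)


def dge_subtype_vs_subtype(pb: PseudobulkTable, subtype_a: str, subtype_b: str,
                           phenotype: str = "control",
                           weights_mode: str = "none", **kw) -> pd.DataFrame:
    """Subtype-vs-subtype contrast within one phenotype (positive = up in a)."""
    a = pb.rows(subtype=subtype_a, phenotype=phenotype)
    b = pb.rows(subtype=subtype_b, phenotype=phenotype)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per subtype")
    name = f"{subtype_a}_vs_{subtype_b}"
    design = _two_group_design(a, b, name)
    return fit_dge(pb, design, name, weights_mode=weights_mode, **kw)


def call_significant(dge: pd.DataFrame, lfc_min: float = 0.1,
                     alpha: float = 0.001,
                     use_adjusted: bool = True) -> pd.Index:
    """Genes with |log2FC| strictly above lfc_min and p strictly below alpha."""
    p = dge["padj"] if use_adjusted else dge["pvalue"]
    keep = (dge["log2fc"].abs() > lfc_min) & (p < alpha)
    return dge.index[keep]


def _pseudobulk_from_blocks(gene_index: pd.Index, blocks: dict,
                            prior: float) -> PseudobulkTable:
    cols = list(blocks)
    sums = np.column_stack([blocks[c][0] for c in cols])
    vars = np.column_stack([blocks[c][1] for c in cols])
    meta = pd.DataFrame([blocks[c][2] for c in cols], index=cols,
                        columns=["sample", "subtype", "phenotype", "n_cells",
                                 "lib_size"])
    counts = pd.DataFrame(sums, index=gene_index, columns=cols)
    log2cpm = np.log2(1e6 * counts / meta["lib_size"].to_numpy() + prior)
    return PseudobulkTable(counts=counts, log2cpm=log2cpm, meta=meta,
                           cell_var=pd.DataFrame(vars, index=gene_index,
                                                 columns=cols), prior=prior)


def bootstrap_dge(adata: ad.AnnData, subtype: str, n_boot: int, seed: int,
                  cells_per_sample: int | None = None, lfc_min: float = 0.1,
                  alpha: float = 0.001, use_adjusted: bool = True,
                  replacement: bool = True,
                  identity_resample: bool = False) -> pd.DataFrame:
    """Bootstrap robustness of the disease contrast for one subtype.

    Each replicate resamples, with replacement, equal numbers of samples per
    phenotype and then equal numbers of cells per sample, repeats the
    pseudobulk fit, and records each gene's call. Returns per gene the
    fraction of replicates significant (``freq_significant``), the majority
    sign fraction among replicates (``sign_consistency``) and the mean
    bootstrap log2FC. ``identity_resample`` short-circuits resampling so a
    single replicate reproduces the plain fit.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    X = X.tocsr()
    obs = adata.obs
    sel = obs["subtype"] == subtype
    cells_by_sample = {
        s: np.flatnonzero(sel.to_numpy() & (obs["sample"] == s).to_numpy())
        for s in obs.loc[sel, "sample"].unique()}
    phen_of = {s: obs.loc[obs["sample"] == s, "phenotype"].iloc[0]
               for s in cells_by_sample}
    by_phen: dict[str, list[str]] = {}
    for s, ph in phen_of.items():
        by_phen.setdefault(ph, []).append(s)
    if set(by_phen) != {"control", "HD"}:
        raise ValueError("both phenotypes required for the bootstrap")
    min_cells = min(len(v) for v in cells_by_sample.values())
    n_cells = cells_per_sample if cells_per_sample is not None else min_cells
    if not replacement and n_cells > min_cells:
        raise ValueError(f"subtype {subtype!r} has a sample with only "
                         f"{min_cells} cells; cannot draw {n_cells} without "
                         "replacement")

    genes = adata.var_names
    sig = np.zeros(len(genes))
    pos = np.zeros(len(genes))
    neg = np.zeros(len(genes))
    lfc_sum = np.zeros(len(genes))
    for _ in range(n_boot):
        blocks = {}
        for ph, samp in sorted(by_phen.items()):
            if identity_resample:
                chosen = list(samp)
            else:
                chosen = list(rng.choice(samp, size=len(samp), replace=True))
            for j, s in enumerate(chosen):
                pool = cells_by_sample[s]
                if identity_resample:
                    idx = pool
                else:
                    idx = rng.choice(pool, size=n_cells, replace=replacement)
                sub = X[idx]
                total = np.asarray(sub.sum(axis=0)).ravel()
                mean = total / len(idx)
                sq = np.asarray(sub.multiply(sub).sum(axis=0)).ravel() / len(idx)
                key = f"{ph}{j}|{subtype}"
                blocks[key] = (total, sq - mean ** 2,
                               (f"{ph}{j}", subtype, ph, len(idx),
                                float(total.sum())))
        pb = _pseudobulk_from_blocks(genes, blocks, DEFAULT_PRIOR)
        res = dge_hd_vs_control(pb, subtype)
        called = np.zeros(len(genes), dtype=bool)
        called[pb.genes.get_indexer(
            call_significant(res, lfc_min, alpha, use_adjusted))] = True
        sig += called
        lfc = res["log2fc"].to_numpy()
        pos += lfc > 0
        neg += lfc < 0
        lfc_sum += lfc
    out = pd.DataFrame(
        {"freq_significant": sig / n_boot,
         "sign_consistency": np.maximum(pos, neg) / n_boot,
         "mean_log2fc": lfc_sum / n_boot},
        index=genes)
    out.attrs["n_boot"] = n_boot
    out.attrs["subtype"] = subtype
    return out
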