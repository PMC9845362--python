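"""Transcriptomic identity distance between SPN subtypes.

Each (subtype, phenotype) group is summarized as a probability vector over
genes (library-normalized per-cell expression, averaged, renormalized to the
simplex). The Jensen-Shannon distance — the square root of the
Jensen-Shannon divergence, a metric bounded in [0, 1] with base-2 logs —
measures how distinct two groups are; the disease-minus-control difference
of that distance per subtype pair ("loss of distinction") is negative where
a pair became more alike. A regression of loss on the endogenous (control)
distance over all pairs flags pairs losing more or less distinction than
expected from their endogenous separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats

from .syndata import compartment_of, pathway_of

SPN_SUBTYPES = ("M-D1", "S-D1", "M-D2", "S-D2", "O-D2")


@dataclass
class SubtypeProfile:
    """Mean expression of one (subtype, phenotype) group on the simplex."""

    subtype: str
    phenotype: str
    p: np.ndarray
    genes: pd.Index
    n_cells: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if (self.p < 0).any():
            raise ValueError("profile has negative entries")
        s = self.p.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"profile sums to {s}, not 1")


def detected_genes(adata: ad.AnnData, min_detect_frac: float = 0.0) -> np.ndarray:
    """Boolean mask of genes detected in at least a fraction of all cells."""
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    frac = np.asarray((X > 0).mean(axis=0)).ravel()
    return frac >= min_detect_frac


def subtype_profile(adata: ad.AnnData, subtype: str, phenotype: str,
                    gene_mask: np.ndarray | None = None,
                    normalization: str = "cpm_mean") -> SubtypeProfile:
    """Average gene expression vector of one group, on the simplex.

    ``normalization``: 'cpm_mean' (default; per-cell counts divided by the
    cell's library, then averaged), 'raw_mean' (plain mean counts) or
    'log1p_mean' (mean of log1p CPM). The result is renormalized to sum 1.
    """
    sel = ((adata.obs["subtype"] == subtype)
           & (adata.obs["phenotype"] == phenotype)).to_numpy()
    if not sel.any():
        raise ValueError(f"no cells for ({subtype}, {phenotype})")
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    X = X[sel]
    if gene_mask is not None:
        X = X[:, gene_mask]
        genes = adata.var_names[gene_mask]
    else:
        genes = adata.var_names
    lib = np.asarray(X.sum(axis=1)).ravel()
    if normalization == "cpm_mean":
        vals = X.multiply(1.0 / np.maximum(lib, 1)[:, None]).mean(axis=0)
        mean = np.asarray(vals).ravel()
    elif normalization == "raw_mean":
        mean = np.asarray(X.mean(axis=0)).ravel()
    elif normalization == "log1p_mean":
        cpm = X.multiply(1e4 / np.maximum(lib, 1)[:, None]).tocsr()
        cpm.data = np.log1p(cpm.data)
        mean = np.asarray(cpm.mean(axis=0)).ravel()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    total = mean.sum()
    if total <= 0:
        raise ValueError("group has zero total expression")
    return SubtypeProfile(subtype=subtype, phenotype=phenotype, p=mean / total,
                          genes=genes, n_cells=int(sel.sum()))


def js_distance(p: np.ndarray, q: np.ndarray, log_base: float = 2.0) -> float:
    """Jensen-Shannon distance: sqrt(0.5 KL(P||M) + 0.5 KL(Q||M)), M=(P+Q)/2.

    With base-2 logarithms the distance lies in [0, 1]; 0*log(0) := 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("P and Q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("P and Q must be non-negative")
    for name, v in (("P", p), ("Q", q)):
        if not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} does not sum to 1")
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(p > 0, p * np.log(p / m), 0.0)
        t2 = np.where(q > 0, q * np.log(q / m), 0.0)
    jsd = 0.5 * (t1.sum() + t2.sum()) / np.log(log_base)
    return float(np.sqrt(max(jsd, 0.0)))


def pair_axis(subtype_a: str, subtype_b: str) -> str:
    """Classify a subtype pair: 'S-M', 'D1-D2', 'mixed' or 'other'."""
    try:
        same_comp = compartment_of(subtype_a) == compartment_of(subtype_b)
        same_path = pathway_of(subtype_a) == pathway_of(subtype_b)
    except ValueError:
        return "other"
    if same_path and not same_comp:
        return "S-M"
    if same_comp and not same_path:
        return "D1-D2"
    return "mixed"


def distance_loss(profiles_control: Mapping[str, SubtypeProfile],
                  profiles_condition: Mapping[str, SubtypeProfile],
                  log_base: float = 2.0) -> pd.DataFrame:
    """JS distance per unordered subtype pair in each phenotype, and the loss.

    loss = d_condition - d_control; negative values mean the pair became
    more alike in the condition. Subtypes present in only one phenotype are
    skipped with a warning.
    """
    shared = sorted(set(profiles_control) & set(profiles_condition))
    only = set(profiles_control) ^ set(profiles_condition)
    if only:
        warnings.warn(f"subtypes present in one phenotype only, skipped: "
                      f"{sorted(only)}")
    rows = []
    for a, b in combinations(shared, 2):
        d_ctl = js_distance(profiles_control[a].p, profiles_control[b].p,
                            log_base)
        d_cnd = js_distance(profiles_condition[a].p, profiles_condition[b].p,
                            log_base)
        rows.append((a, b, d_ctl, d_cnd, d_cnd - d_ctl, pair_axis(a, b)))
    return pd.DataFrame(rows, columns=["subtype_a", "subtype_b", "d_control",
                                       "d_condition", "loss", "pair_axis"])


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        raise ValueError("need >= 2 data points for a confidence interval")
    half = stats.t.ppf(0.5 + level / 2, n - 1) * np.std(values, ddof=1) / np.sqrt(n)
    return mean, mean - half, mean + half


def per_celltype_mean_loss(losses: pd.DataFrame,
                           exclude: Sequence[str] = ("O-D2",),
                           ci_level: float = 0.95) -> pd.DataFrame:
    """Mean loss from each subtype toward the others (self and ``exclude``
    excluded as targets), with a t-based confidence interval."""
    subtypes = sorted(set(losses["subtype_a"]) | set(losses["subtype_b"]))
    rows = []
    for t in subtypes:
        sel = (losses["subtype_a"] == t) | (losses["subtype_b"] == t)
        other = np.where(losses["subtype_a"] == t, losses["subtype_b"],
                         losses["subtype_a"])
        keep = sel.to_numpy() & ~np.isin(other, list(exclude))
        vals = losses.loc[keep, "loss"].to_numpy()
        mean, lo, hi = _t_ci(vals, ci_level)
        rows.append((t, mean, lo, hi, len(vals)))
    return pd.DataFrame(rows, columns=["subtype", "mean_loss", "ci_low",
                                       "ci_high", "n"]).set_index("subtype")


@dataclass
class LossRegression:
    """OLS of loss on endogenous control distance with a pointwise CI band."""

    order: int
    ci_level: float
    params: np.ndarray
    r_squared: float
    table: pd.DataFrame  # per pair: fitted, band_low, band_high, flag
    axis_flags: dict

    def to_dict(self) -> dict:
        return {
            "order": self.order, "ci_level": self.ci_level,
            "params": [float(x) for x in self.params],
            "r_squared": float(self.r_squared),
            "axis_flags": self.axis_flags,
            "pairs": [
                {"pair": f"{r.subtype_a}~{r.subtype_b}",
                 "d_control": float(r.d_control), "loss": float(r.loss),
                 "fitted": float(r.fitted), "band_low": float(r.band_low),
                 "band_high": float(r.band_high), "flag": r.flag}
                for r in self.table.itertuples()],
        }


def loss_vs_endogenous_regression(losses: pd.DataFrame, order: int = 1,
                                  ci_level: float = 0.99) -> LossRegression:
    """Regress loss on endogenous distance; flag pairs against the CI band.

    The band is the pointwise confidence interval for the mean response at
    the chosen level. Each pair is flagged 'above', 'within' or 'below' it;
    flags for the S-M and D1-D2 pairs are summarized in ``axis_flags``.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if len(losses) < order + 2:
        raise ValueError("too few pairs for the requested polynomial order")
    x = losses["d_control"].to_numpy()
    if np.allclose(x, x[0]):
        raise ValueError("degenerate predictor: all endogenous distances equal")
    y = losses["loss"].to_numpy()
    X = np.column_stack([np.ones_like(x)] + [x ** k for k in range(1, order + 1)])
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X)
    band = pred.conf_int(alpha=1.0 - ci_level)
    table = losses.copy()
    table["fitted"] = pred.predicted_mean
    table["band_low"] = band[:, 0]
    table["band_high"] = band[:, 1]
    table["flag"] = np.where(y < band[:, 0], "below",
                             np.where(y > band[:, 1], "above", "within"))
    axis_flags = {
        axis: {f"{r.subtype_a}~{r.subtype_b}": r.flag
               for r in table[table["pair_axis"] == axis].itertuples()}
        for axis in ("S-M", "D1-D2")}
    return LossRegression(order=order, ci_level=ci_level, params=fit.params,
                          r_squared=fit.rsquared, table=table,
                          axis_flags=axis_flags)


def subtype_fractions(adata: ad.AnnData,
                      universe: Sequence[str] = SPN_SUBTYPES) -> pd.DataFrame:
    """Per-phenotype SPN subtype fractions and the disease-minus-control change."""
    obs = adata.obs
    unknown = [t for t in universe if t not in set(obs["subtype"])]
    if unknown:
        raise ValueError(f"unknown subtype labels in universe: {unknown}")
    sel = obs["subtype"].isin(universe)
    rows = {}
    for ph in ("control", "HD"):
        grp = obs.loc[sel & (obs["phenotype"] == ph), "subtype"]
        if grp.empty:
            raise ValueError(f"no SPN cells for phenotype {ph!r}")
        counts = grp.value_counts().reindex(universe).fillna(0)
        rows[ph] = counts / counts.sum()
    out = pd.DataFrame({"fraction_control": rows["control"],
                        "fraction_hd": rows["HD"]})
    out["change"] = out["fraction_hd"] - out["fraction_control"]
    out.index.name = "subtype"
    return out
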