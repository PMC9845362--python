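"""Directionality and severity of disease dysregulation across subtypes.

A gene dysregulated in the disease phenotype is *unidirectional* when its
log2FC carries one sign across the four canonical SPN subtypes (M-D1, S-D1,
M-D2, S-D2) and *bidirectional* when both signs occur — i.e., cell-type
specific. The unidirectional gate requires |log2FC| > lfc_min and p < alpha
in at least one canonical subtype; the bidirectional gate requires p < alpha
in at least one (a harmonized mode applies both thresholds to both classes).
O-D2 contributes to severity summaries but not to the four-type sign
pattern. Severity is the mean |log2FC| per subtype, compared by one-way
ANOVA with Tukey-Kramer post-hoc pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .syndata import CANONICAL_SUBTYPES

CLASSES = ("unidirectional", "bidirectional", "not-dysregulated")


def dge_tables_to_matrices(dge_by_subtype: dict[str, pd.DataFrame],
                           use_adjusted: bool = True,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-subtype DGE tables into genes x subtypes lfc and p tables."""
    genes = None
    for t, d in dge_by_subtype.items():
        genes = d.index if genes is None else genes.union(d.index)
    pcol = "padj" if use_adjusted else "pvalue"
    lfc = pd.DataFrame({t: d["log2fc"].reindex(genes)
                        for t, d in dge_by_subtype.items()})
    p = pd.DataFrame({t: d[pcol].reindex(genes)
                      for t, d in dge_by_subtype.items()})
    return lfc, p


def classify_directionality(dge_by_subtype: dict[str, pd.DataFrame],
                            lfc_min: float = 0.1, alpha: float = 0.001,
                            use_adjusted: bool = False,
                            mode: str = "as-described",
                            zero_policy: str = "majority",
                            canonical=CANONICAL_SUBTYPES) -> pd.DataFrame:
    """Assign each gene a directionality class from per-subtype DGE tables.

    Returns a per-gene table with ``class``, per-subtype ``lfc_<t>`` columns
    (all supplied subtypes, canonical or not) and ``qualifying`` — the
    canonical subtypes whose significance admitted the gene. ``mode``
    'as-described' uses the class-specific gates described above;
    'harmonized' applies |log2FC| > lfc_min AND p < alpha to both classes.
    ``zero_policy`` 'majority' lets zero log2FCs side with the nonzero signs;
    'strict' treats a zero as incompatible with unidirectionality.
    """
    missing = [t for t in canonical if t not in dge_by_subtype]
    if missing:
        raise ValueError(f"missing DGE tables for canonical subtypes: {missing}")
    if mode not in ("as-described", "harmonized"):
        raise ValueError(f"unknown mode {mode!r}")
    lfc, p = dge_tables_to_matrices(dge_by_subtype, use_adjusted)
    L = lfc[list(canonical)].to_numpy()
    P = p[list(canonical)].to_numpy()

    has_pos = (L > 0).any(axis=1)
    has_neg = (L < 0).any(axis=1)
    has_zero = (L == 0).any(axis=1)
    bidirectional_pattern = has_pos & has_neg
    if zero_policy == "strict":
        unidirectional_pattern = (has_pos ^ has_neg) & ~has_zero
    elif zero_policy == "majority":
        unidirectional_pattern = has_pos ^ has_neg
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    sig_strict = (np.abs(L) > lfc_min) & (P < alpha)
    sig_ponly = P < alpha
    gate_uni = np.nan_to_num(sig_strict, nan=0).astype(bool).any(axis=1)
    if mode == "harmonized":
        gate_bi = gate_uni
    else:
        gate_bi = np.nan_to_num(sig_ponly, nan=0).astype(bool).any(axis=1)

    cls = np.full(len(lfc), "not-dysregulated", dtype=object)
    cls[unidirectional_pattern & gate_uni] = "unidirectional"
    cls[bidirectional_pattern & gate_bi] = "bidirectional"

    qual = []
    gate_mat = np.where((cls == "bidirectional")[:, None], sig_ponly, sig_strict)
    for i in range(len(lfc)):
        if cls[i] == "not-dysregulated":
            qual.append("")
        else:
            qual.append(",".join(c for j, c in enumerate(canonical)
                                 if gate_mat[i, j]))
    out = pd.DataFrame({"class": cls, "qualifying": qual}, index=lfc.index)
    for t in lfc.columns:
        out[f"lfc_{t}"] = lfc[t]
    out.attrs["canonical"] = tuple(canonical)
    return out


def _lfc_matrix(records: pd.DataFrame, subtypes) -> pd.DataFrame:
    cols = {t: records[f"lfc_{t}"] for t in subtypes}
    return pd.DataFrame(cols)


def _anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA; all-identical observations give F=0, p=1."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    if df_w <= 0:
        raise ValueError("not enough observations for ANOVA")
    if ss_within <= 1e-300:
        if ss_between <= 1e-300:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(stats.f.sf(F, df_b, df_w))


@dataclass
class SeveritySummary:
    """Per-subtype severity with ANOVA and Tukey-Kramer pairwise tests."""

    means: pd.DataFrame  # per subtype: mean, ci_low, ci_high, n
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # pair, meandiff, p_adj, reject
    n_genes: int
    subset: str = ""

    def to_dict(self) -> dict:
        return {
            "subset": self.subset, "n_genes": int(self.n_genes),
            "anova_f": float(self.anova_f), "anova_p": float(self.anova_p),
            "means": {t: {k: float(v) for k, v in row.items()}
                      for t, row in self.means.iterrows()},
            "tukey": [{"pair": f"{r.group1}~{r.group2}",
                       "meandiff": float(r.meandiff),
                       "p_adj": float(r.p_adj), "reject": bool(r.reject)}
                      for r in self.tukey.itertuples()],
        }


def severity_by_celltype(records: pd.DataFrame, subtypes,
                         directionality: str = "all",
                         genes: pd.Index | None = None,
                         signed: bool = False,
                         ci_level: float = 0.95) -> SeveritySummary:
    """Mean |log2FC| per subtype over a gene subset, with ANOVA + Tukey.

    ``directionality`` restricts to one class ('all', 'unidirectional',
    'bidirectional'); ``genes`` optionally restricts further (e.g., to a
    marker catalog). Observations are genes; groups are subtypes.
    """
    sel = records
    if directionality != "all":
        sel = sel[sel["class"] == directionality]
    if genes is not None:
        sel = sel.loc[sel.index.intersection(genes)]
    if len(sel) < 2:
        raise ValueError("fewer than 2 genes in the requested subset")
    M = _lfc_matrix(sel, subtypes)
    V = M.to_numpy() if signed else np.abs(M.to_numpy())

    rows = []
    groups, labels = [], []
    for j, t in enumerate(subtypes):
        vals = V[:, j]
        vals = vals[~np.isnan(vals)]
        n = len(vals)
        mean = float(vals.mean())
        half = (stats.t.ppf(0.5 + ci_level / 2, n - 1)
                * np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append((t, mean, mean - half, mean + half, n))
        groups.append(vals)
        labels.extend([t] * n)
    means = pd.DataFrame(rows, columns=["subtype", "mean", "ci_low", "ci_high",
                                        "n"]).set_index("subtype")
    F, pval = _anova_oneway(groups)
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:  # identical everywhere: no pairwise differences
        tukey = pd.DataFrame([(a, b, 0.0, 1.0, False)
                              for i, a in enumerate(subtypes)
                              for b in list(subtypes)[i + 1:]],
                             columns=["group1", "group2", "meandiff", "p_adj",
                                      "reject"])
    else:
        res = pairwise_tukeyhsd(allv, np.array(labels), alpha=0.05)
        tukey = pd.DataFrame(res.summary().data[1:],
                             columns=[c.replace("-", "_") for c in
                                      res.summary().data[0]])
        tukey = tukey.rename(columns={"p_adj": "p_adj"})[
            ["group1", "group2", "meandiff", "p_adj", "reject"]]
    return SeveritySummary(means=means, anova_f=F, anova_p=pval,
                           tukey=tukey, n_genes=len(sel),
                           subset=directionality)


def marker_direction_summary(records: pd.DataFrame, marker_catalog: pd.DataFrame,
                             subtypes, ci_level: float = 0.95) -> pd.DataFrame:
    """Mean disease log2FC per (marker side, scope group, subtype) with CI.

    The blurring diagnosis reads off the sign pattern: compartmental (S-M)
    marker sides show opposite signs in striosomal vs matrix subtypes,
    pathway (D1-D2) sides do not flip sign across cell types.
    """
    if marker_catalog.empty:
        raise ValueError("empty marker catalog")
    rows = []
    for (axis, side), grp in marker_catalog.groupby(["axis", "side"]):
        for scope_class in ("universal", "selective", "all"):
            if scope_class == "universal":
                g = grp[grp["scope"] == "universal"]
            elif scope_class == "selective":
                g = grp[grp["scope"] != "universal"]
            else:
                g = grp
            shared = records.index.intersection(g.index)
            if len(shared) < 2:
                continue
            M = _lfc_matrix(records.loc[shared], subtypes)
            for t in subtypes:
                vals = M[t].dropna().to_numpy()
                if len(vals) < 2:
                    continue
                mean = float(vals.mean())
                half = (stats.t.ppf(0.5 + ci_level / 2, len(vals) - 1)
                        * np.std(vals, ddof=1) / np.sqrt(len(vals)))
                rows.append((axis, side, scope_class, t, mean, mean - half,
                             mean + half, len(vals)))
    return pd.DataFrame(rows, columns=["axis", "side", "scope", "subtype",
                                       "mean_lfc", "ci_low", "ci_high", "n"])


def gene_set_summary(dge_by_subtype: dict[str, pd.DataFrame], gene_list,
                     ci_level: float = 0.95) -> pd.DataFrame:
    """Per-subtype mean log2FC of a gene set, counting quantifiable genes.

    A gene is quantifiable in a subtype when that subtype's table holds a
    finite estimate for it. Reports n_used of n_supplied per subtype.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene_list is empty")
    rows = []
    any_used = 0
    for t, d in dge_by_subtype.items():
        vals = d["log2fc"].reindex(gene_list).dropna()
        vals = vals[np.isfinite(vals)]
        n = len(vals)
        any_used = max(any_used, n)
        if n == 0:
            rows.append((t, np.nan, np.nan, np.nan, 0, len(gene_list)))
            continue
        mean = float(vals.mean())
        if n > 1:
            half = (stats.t.ppf(0.5 + ci_level / 2, n - 1)
                    * np.std(vals, ddof=1) / np.sqrt(n))
        else:
            half = np.nan
        rows.append((t, mean, mean - half, mean + half, n, len(gene_list)))
    if any_used == 0:
        raise ValueError("no quantifiable genes in any subtype")
    return pd.DataFrame(rows, columns=["subtype", "mean_lfc", "ci_low",
                                       "ci_high", "n_used", "n_supplied"]
                        ).set_index("subtype")


def cross_model_concordance(records_a: pd.DataFrame, records_b: pd.DataFrame,
                            directionality: str, subtypes) -> dict:
    """Compare per-subtype severity between two disease models.

    Returns the two per-subtype mean |log2FC| vectors for the chosen class,
    their Kendall rank concordance over subtypes, and the fraction of genes
    in the class in both models whose mean canonical log2FC agrees in sign.
    """
    for r in (records_a, records_b):
        missing = [t for t in subtypes if f"lfc_{t}" not in r.columns]
        if missing:
            raise ValueError(f"records missing subtypes: {missing}")
    sel_a = records_a[records_a["class"] == directionality]
    sel_b = records_b[records_b["class"] == directionality]
    sev_a = np.abs(_lfc_matrix(sel_a, subtypes)).mean(axis=0)
    sev_b = np.abs(_lfc_matrix(sel_b, subtypes)).mean(axis=0)
    tau = stats.kendalltau(sev_a.to_numpy(), sev_b.to_numpy()).statistic

    shared = sel_a.index.intersection(sel_b.index)
    canonical = records_a.attrs.get("canonical", CANONICAL_SUBTYPES)
    canonical = [t for t in canonical if t in subtypes]
    if len(shared):
        ma = _lfc_matrix(sel_a.loc[shared], canonical).mean(axis=1)
        mb = _lfc_matrix(sel_b.loc[shared], canonical).mean(axis=1)
        ok = (np.sign(ma) != 0) & (np.sign(mb) != 0)
        agree = float((np.sign(ma[ok]) == np.sign(mb[ok])).mean()) if ok.any() \
            else float("nan")
    else:
        agree = float("nan")
    return {"severity_a": {t: float(v) for t, v in sev_a.items()},
            "severity_b": {t: float(v) for t, v in sev_b.items()},
            "kendall_tau": float(tau), "sign_agreement": agree,
            "n_shared": int(len(shared))}
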