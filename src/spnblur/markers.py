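"""Axis marker identification and cross-dataset conservation.

A striosome-matrix (S-M) marker is a gene whose expression differs between
compartments in the control phenotype; the defining contrasts are S-D1 vs
M-D1 (the D1 population) and S-D2 vs M-D2 (the D2 population). A marker is
*universal* when both contrasts pass the thresholds with the same sign and
*selective* when exactly one passes. The D1-D2 axis is handled by the same
operation with defining contrasts S-D1 vs S-D2 (striosome population) and
M-D1 vs M-D2 (matrix population). Genes passing both contrasts with opposite
signs are excluded from both sides and reported separately. O-D2 takes part
in no defining contrast.

Conservation across datasets (e.g., species) is quantified as Venn overlap
counts per marker class, sign-quadrant concordance of the compartmental
log2FC, and a hyper-conserved list (universal, same side, in every dataset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AXIS_SIDES = {"S-M": ("striosome", "matrix"), "D1-D2": ("D1", "D2")}
# scope suffix names the population whose contrast passed
AXIS_POPULATIONS = {"S-M": ("D1", "D2"), "D1-D2": ("S", "M")}

MARKER_COLUMNS = ("axis", "side", "scope", "lfc_a", "p_a", "lfc_b", "p_b",
                  "flagged_partial", "dataset")


def identify_axis_markers(dge_a: pd.DataFrame, dge_b: pd.DataFrame,
                          axis: str = "S-M", lfc_min: float = 0.1,
                          alpha: float = 0.001, use_adjusted: bool = True,
                          dataset: str = "") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify markers from the two defining contrasts of one axis.

    ``dge_a``/``dge_b`` are DGE tables whose positive log2FC favors the
    axis's first side (striosome for 'S-M', D1 for 'D1-D2') in the first and
    second defining population respectively. Returns ``(markers, discordant)``
    where discordant genes pass both contrasts with opposite signs.
    A gene present in only one table is classified from that contrast alone
    and flagged (``flagged_partial``).
    """
    if axis not in AXIS_SIDES:
        raise ValueError(f"unknown axis {axis!r}")
    pos_side, neg_side = AXIS_SIDES[axis]
    pop_a, pop_b = AXIS_POPULATIONS[axis]
    pcol = "padj" if use_adjusted else "pvalue"

    all_genes = dge_a.index.union(dge_b.index)
    lfc_a = dge_a["log2fc"].reindex(all_genes)
    p_a = dge_a[pcol].reindex(all_genes)
    lfc_b = dge_b["log2fc"].reindex(all_genes)
    p_b = dge_b[pcol].reindex(all_genes)

    pass_a = (lfc_a.abs() > lfc_min) & (p_a < alpha)
    pass_b = (lfc_b.abs() > lfc_min) & (p_b < alpha)
    pass_a = pass_a.fillna(False)
    pass_b = pass_b.fillna(False)

    rows, discordant_rows = [], []
    for g in all_genes:
        a, b = bool(pass_a[g]), bool(pass_b[g])
        if not (a or b):
            continue
        partial = bool(pd.isna(lfc_a[g]) or pd.isna(lfc_b[g]))
        if a and b:
            if np.sign(lfc_a[g]) != np.sign(lfc_b[g]):
                discordant_rows.append((g, lfc_a[g], p_a[g], lfc_b[g], p_b[g]))
                continue
            scope = "universal"
            sign = np.sign(lfc_a[g])
        elif a:
            scope = f"selective-{pop_a}"
            sign = np.sign(lfc_a[g])
        else:
            scope = f"selective-{pop_b}"
            sign = np.sign(lfc_b[g])
        side = pos_side if sign > 0 else neg_side
        rows.append((g, axis, side, scope, lfc_a[g], p_a[g], lfc_b[g], p_b[g],
                     partial, dataset))
    markers = pd.DataFrame(rows, columns=("gene",) + MARKER_COLUMNS)
    markers = markers.set_index("gene")
    discordant = pd.DataFrame(
        discordant_rows, columns=["gene", "lfc_a", "p_a", "lfc_b", "p_b"]
    ).set_index("gene")
    return markers, discordant


@dataclass
class ConservationSummary:
    """Cross-dataset marker conservation for one axis.

    venn : per (side, scope-class) dict of Venn cell counts keyed by
        membership signature (e.g., 'a', 'ab', 'abc').
    quadrant : concordant / discordant counts of shared genes by the sign of
        their compartmental (or pathway) log2FC in each dataset.
    hyper_conserved : genes universal with the same side in every dataset.
    """

    venn: dict = field(default_factory=dict)
    quadrant: dict = field(default_factory=dict)
    hyper_conserved: list = field(default_factory=list)
    n_unmapped: int = 0

    def to_dict(self) -> dict:
        return {"venn": self.venn, "quadrant": self.quadrant,
                "hyper_conserved": sorted(self.hyper_conserved),
                "n_unmapped": int(self.n_unmapped)}


def _apply_ortholog_map(markers: pd.DataFrame,
                        ortholog_map: pd.DataFrame | None) -> tuple[pd.DataFrame, int]:
    """Rename genes into the reference namespace via a strict 1:1 map."""
    if ortholog_map is None:
        return markers, 0
    if ortholog_map.shape[1] < 2:
        raise ValueError("ortholog map needs two columns: source, reference")
    src = ortholog_map.iloc[:, 0].astype(str)
    ref = ortholog_map.iloc[:, 1].astype(str)
    bad = sorted(set(src[src.duplicated(keep=False)])
                 | set(ref[ref.duplicated(keep=False)]))
    if bad:
        raise ValueError(f"ortholog map is not one-to-one; offending ids: {bad}")
    mapping = dict(zip(src, ref))
    mapped = markers.index.map(mapping.get)
    keep = mapped.notna()
    out = markers.loc[keep].copy()
    out.index = pd.Index(mapped[keep], name="gene")
    return out, int((~keep).sum())


def _venn_counts(sets: dict[str, set]) -> dict[str, int]:
    labels = list(sets)
    union = set().union(*sets.values())
    cells: dict[str, int] = {}
    for g in union:
        key = "".join(lb for lb in labels if g in sets[lb])
        cells[key] = cells.get(key, 0) + 1
    return dict(sorted(cells.items()))


def conservation_overlap(markers_a: pd.DataFrame, markers_b: pd.DataFrame,
                         markers_c: pd.DataFrame | None = None,
                         ortholog_map_b: pd.DataFrame | None = None,
                         ortholog_map_c: pd.DataFrame | None = None,
                         ) -> ConservationSummary:
    """Conservation of one axis's markers across 2-3 datasets.

    Non-reference marker tables are translated into the reference (dataset a)
    gene namespace through strict one-to-one ortholog maps (columns: source
    id, reference id); unmapped genes are dropped and counted. Conservation
    in the Venn and hyper-conserved senses requires the same side, not mere
    presence; the quadrant analysis classifies genes that are markers in at
    least two datasets by the concordance of their signed log2FC.
    """
    datasets = {"a": markers_a}
    markers_b, miss_b = _apply_ortholog_map(markers_b, ortholog_map_b)
    datasets["b"] = markers_b
    miss_c = 0
    if markers_c is not None:
        markers_c, miss_c = _apply_ortholog_map(markers_c, ortholog_map_c)
        datasets["c"] = markers_c

    summary = ConservationSummary(n_unmapped=miss_b + miss_c)
    axes = set().union(*(set(m["axis"].unique()) for m in datasets.values()))
    for axis in sorted(axes):
        for side in AXIS_SIDES.get(axis, ()):
            for scope_class in ("universal", "any"):
                sets = {}
                for lb, m in datasets.items():
                    sel = (m["axis"] == axis) & (m["side"] == side)
                    if scope_class == "universal":
                        sel &= m["scope"] == "universal"
                    sets[lb] = set(m.index[sel])
                summary.venn[f"{axis}|{side}|{scope_class}"] = _venn_counts(sets)

    # sign-quadrant concordance over genes marker-called in >= 2 datasets
    def signed_lfc(m: pd.DataFrame) -> pd.Series:
        return m[["lfc_a", "lfc_b"]].mean(axis=1, skipna=True)

    pairs = [("a", "b")] + ([("a", "c"), ("b", "c")] if markers_c is not None
                            else [])
    for la, lb in pairs:
        ma, mb = datasets[la], datasets[lb]
        shared = ma.index.intersection(mb.index)
        conc = disc = 0
        for g in shared:
            sa = np.sign(signed_lfc(ma.loc[[g]]).iloc[0])
            sb = np.sign(signed_lfc(mb.loc[[g]]).iloc[0])
            if sa == 0 or sb == 0:
                continue
            if sa == sb:
                conc += 1
            else:
                disc += 1
        summary.quadrant[f"{la}-{lb}"] = {"concordant": conc,
                                          "discordant": disc,
                                          "n_shared": int(len(shared))}

    # hyper-conserved: universal with identical side in every dataset
    hyper: set | None = None
    for m in datasets.values():
        uni = m[m["scope"] == "universal"]
        tags = {(g, uni.loc[g, "axis"], uni.loc[g, "side"]) for g in uni.index}
        hyper = tags if hyper is None else hyper & tags
    summary.hyper_conserved = sorted({g for g, _, _ in (hyper or set())})
    return summary


def export_gene_lists(markers: pd.DataFrame, outdir) -> list:
    """Write one plain gene-per-line list per (axis, side, scope) class."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for (axis, side, scope), grp in markers.groupby(["axis", "side", "scope"]):
        name = f"{axis}_{side}_{scope}.txt".replace("/", "-")
        path = outdir / name
        path.write_text("\n".join(sorted(grp.index)) + "\n")
        written.append(path)
    return written
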