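"""Directionality classification, severity ANOVA/Tukey, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spnblur.dysreg import (classify_directionality, cross_model_concordance,
                            gene_set_summary, marker_direction_summary,
                            severity_by_celltype, _anova_oneway)
from spnblur.syndata import CANONICAL_SUBTYPES

SUBTYPES5 = ("M-D1", "S-D1", "M-D2", "S-D2", "O-D2")


def _tables(lfc_rows, p_rows, genes=None):
    """Build per-subtype DGE tables from genes x 4-subtype matrices."""
    lfc_rows = np.atleast_2d(lfc_rows)
    p_rows = np.atleast_2d(p_rows)
    genes = genes or [f"g{i}" for i in range(len(lfc_rows))]
    out = {}
    for j, t in enumerate(CANONICAL_SUBTYPES):
        out[t] = pd.DataFrame({"log2fc": lfc_rows[:, j],
                               "pvalue": p_rows[:, j],
                               "padj": p_rows[:, j]},
                              index=pd.Index(genes, name="gene"))
    return out


class TestClassification:
    def test_unidirectional_all_same_sign(self):
        tabs = _tables([0.2, 0.15, 0.3, 0.12], [1e-5] * 4)
        rec = classify_directionality(tabs)
        assert rec.loc["g0", "class"] == "unidirectional"

    def test_bidirectional_mixed_signs_one_significant(self):
        tabs = _tables([0.2, -0.15, 0.1, -0.05], [1e-5, 0.5, 0.5, 0.5])
        rec = classify_directionality(tabs)
        assert rec.loc["g0", "class"] == "bidirectional"

    def test_no_significance_not_dysregulated(self):
        tabs = _tables([0.2, 0.15, 0.3, 0.12], [0.5] * 4)
        rec = classify_directionality(tabs)
        assert rec.loc["g0", "class"] == "not-dysregulated"

    def test_unidirectional_gate_needs_lfc_floor(self):
        # significant p but tiny effects: fails the |lfc| > 0.1 gate
        tabs = _tables([0.05, 0.04, 0.06, 0.02], [1e-6] * 4)
        rec = classify_directionality(tabs, lfc_min=0.1)
        assert rec.loc["g0", "class"] == "not-dysregulated"
        # harmonized mode applies the same gate to bidirectional genes
        tabs2 = _tables([0.05, -0.04, 0.06, -0.02], [1e-6] * 4)
        assert classify_directionality(tabs2).loc["g0", "class"] \
            == "bidirectional"
        assert classify_directionality(tabs2, mode="harmonized") \
            .loc["g0", "class"] == "not-dysregulated"

    def test_missing_canonical_table_errors(self):
        tabs = _tables([0.2, 0.15, 0.3, 0.12], [1e-5] * 4)
        del tabs["S-D2"]
        with pytest.raises(ValueError, match="S-D2"):
            classify_directionality(tabs)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_bruteforce_scan_agrees(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        lfc = rng.normal(0, 0.2, (n, 4))
        lfc[rng.random((n, 4)) < 0.1] = 0.0
        p = rng.uniform(0, 0.01, (n, 4))
        rec = classify_directionality(_tables(lfc, p), lfc_min=0.1,
                                      alpha=0.001)
        for i in range(n):
            signs = set(np.sign(lfc[i])) - {0.0}
            strict = ((np.abs(lfc[i]) > 0.1) & (p[i] < 0.001)).any()
            ponly = (p[i] < 0.001).any()
            if signs == {1.0, -1.0}:
                expect = "bidirectional" if ponly else "not-dysregulated"
            elif signs:
                expect = "unidirectional" if strict else "not-dysregulated"
            else:
                expect = "not-dysregulated"
            assert rec.iloc[i]["class"] == expect

    def test_partition_every_gene_one_class(self):
        rng = np.random.default_rng(3)
        lfc = rng.normal(0, 0.3, (200, 4))
        p = rng.uniform(0, 0.05, (200, 4))
        rec = classify_directionality(_tables(lfc, p))
        assert rec["class"].isin(["unidirectional", "bidirectional",
                                  "not-dysregulated"]).all()
        assert len(rec) == 200


def _records(lfc_matrix, cls, subtypes=SUBTYPES5):
    genes = [f"g{i}" for i in range(len(lfc_matrix))]
    rec = pd.DataFrame({"class": cls, "qualifying": ""},
                       index=pd.Index(genes, name="gene"))
    for j, t in enumerate(subtypes):
        rec[f"lfc_{t}"] = np.asarray(lfc_matrix)[:, j]
    rec.attrs["canonical"] = CANONICAL_SUBTYPES
    return rec


class TestSeverity:
    def test_identical_values_give_f_zero_p_one(self):
        rec = _records(np.full((5, 5), 0.3), ["unidirectional"] * 5)
        out = severity_by_celltype(rec, SUBTYPES5)
        assert out.anova_f == 0.0 and out.anova_p == 1.0
        assert not out.tukey["reject"].any()

    def test_two_group_anova_equals_squared_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        F, p = _anova_oneway([a, b])
        t, pt = stats.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t ** 2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        L = rng.normal(0, 0.3, (40, 5))
        rec = _records(L, ["bidirectional"] * 40)
        out1 = severity_by_celltype(rec, SUBTYPES5,
                                    directionality="bidirectional")
        perm = rng.permutation(40)
        out2 = severity_by_celltype(rec.iloc[perm], SUBTYPES5,
                                    directionality="bidirectional")
        pd.testing.assert_frame_equal(out1.means, out2.means)

    def test_empty_subset_errors(self):
        rec = _records(np.ones((3, 5)), ["unidirectional"] * 3)
        with pytest.raises(ValueError, match="fewer than 2"):
            severity_by_celltype(rec, SUBTYPES5,
                                 directionality="bidirectional")

    def test_tukey_familywise_error_on_null(self):
        # 500 null one-way ANOVAs, 5 groups x 8 obs: family-wise rejection
        # rate must stay near/below the nominal 0.05
        rng = np.random.default_rng(42)
        hits = 0
        n_fam = 500
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        labels = np.repeat([f"t{j}" for j in range(5)], 8)
        for _ in range(n_fam):
            vals = rng.normal(0, 1, 40)
            res = pairwise_tukeyhsd(vals, labels, alpha=0.05)
            hits += bool(res.reject.any())
        upper = 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n_fam)
        assert hits / n_fam <= upper


class TestMarkerDirection:
    def test_blurring_sign_pattern_recovered(self):
        # striosome markers: down in S subtypes, up in M subtypes
        L = np.array([[0.3, -0.3, 0.3, -0.3, -0.5]] * 10)  # M,S,M,S,O order
        rec = _records(L, ["bidirectional"] * 10)
        catalog = pd.DataFrame({
            "axis": "S-M", "side": "striosome", "scope": "universal"},
            index=rec.index)
        out = marker_direction_summary(rec, catalog, SUBTYPES5)
        uni = out[out.scope == "universal"].set_index("subtype")
        assert uni.loc["S-D1", "mean_lfc"] < 0 < uni.loc["M-D1", "mean_lfc"]
        assert uni.loc["O-D2", "mean_lfc"] < 0

    def test_empty_catalog_errors(self):
        rec = _records(np.ones((3, 5)), ["unidirectional"] * 3)
        with pytest.raises(ValueError, match="empty"):
            marker_direction_summary(rec, pd.DataFrame(), SUBTYPES5)


class TestGeneSet:
    def _tables5(self, lfc, genes):
        return {t: pd.DataFrame({"log2fc": lfc[:, j]},
                                index=pd.Index(genes, name="gene"))
                for j, t in enumerate(SUBTYPES5)}

    def test_unquantifiable_genes_counted(self):
        genes = [f"g{i}" for i in range(3)]
        tabs = self._tables5(np.ones((3, 5)) * 0.2, genes)
        out = gene_set_summary(tabs, genes + ["missing1", "missing2"])
        assert (out["n_used"] == 3).all()
        assert (out["n_supplied"] == 5).all()
        assert out.loc["M-D1", "mean_lfc"] == pytest.approx(0.2)

    def test_hand_mean_on_toy_table(self):
        genes = list("abcd")
        lfc = np.array([[0.1], [0.2], [0.3], [-0.2]]) @ np.ones((1, 5))
        out = gene_set_summary(self._tables5(lfc, genes), genes)
        assert out.loc["S-D2", "mean_lfc"] == pytest.approx(0.1)

    def test_no_quantifiable_errors(self):
        tabs = self._tables5(np.ones((2, 5)), ["x", "y"])
        with pytest.raises(ValueError, match="quantifiable"):
            gene_set_summary(tabs, ["absent"])

    def test_empty_list_errors(self):
        tabs = self._tables5(np.ones((2, 5)), ["x", "y"])
        with pytest.raises(ValueError, match="empty"):
            gene_set_summary(tabs, [])


class TestConcordance:
    def test_identical_models_perfect_concordance(self):
        rng = np.random.default_rng(2)
        L = rng.normal(0, 0.4, (30, 5)) + [0.1, 0.2, 0.3, 0.4, 0.5]
        rec = _records(L, ["bidirectional"] * 30)
        out = cross_model_concordance(rec, rec.copy(), "bidirectional",
                                      SUBTYPES5)
        assert out["kendall_tau"] == pytest.approx(1.0)
        assert out["sign_agreement"] == pytest.approx(1.0)

    def test_independent_nulls_center_tau_at_zero(self):
        rng = np.random.default_rng(7)
        taus = []
        for _ in range(60):
            a = _records(rng.normal(0, 0.3, (40, 5)), ["bidirectional"] * 40)
            b = _records(rng.normal(0, 0.3, (40, 5)), ["bidirectional"] * 40)
            taus.append(cross_model_concordance(a, b, "bidirectional",
                                                SUBTYPES5)["kendall_tau"])
        assert abs(np.mean(taus)) < 0.2

    def test_subtype_mismatch_errors(self):
        rec = _records(np.ones((3, 5)), ["unidirectional"] * 3)
        with pytest.raises(ValueError, match="missing"):
            cross_model_concordance(rec, rec, "unidirectional",
                                    ("M-D1", "NOT-THERE"))
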