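"""Jensen-Shannon identity distance, loss tables, regression and fractions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon
from scipy import stats

from spnblur.identity import (SubtypeProfile, distance_loss, js_distance,
                              loss_vs_endogenous_regression, pair_axis,
                              per_celltype_mean_loss, subtype_fractions,
                              subtype_profile)
from conftest import make_adata


class TestProfiles:
    def test_single_cell_profile(self):
        adata = make_adata([[2, 2, 0]], ["s1"], ["control"], ["M-D1"])
        prof = subtype_profile(adata, "M-D1", "control")
        np.testing.assert_allclose(prof.p, [0.5, 0.5, 0.0])

    def test_equal_library_symmetry(self):
        adata = make_adata([[4, 0], [0, 4]], ["s1"] * 2, ["control"] * 2,
                           ["M-D1"] * 2)
        prof = subtype_profile(adata, "M-D1", "control")
        np.testing.assert_allclose(prof.p, [0.5, 0.5])

    def test_cell_order_invariance(self, small_dataset):
        adata, _ = small_dataset
        perm = np.random.default_rng(1).permutation(adata.n_obs)
        p1 = subtype_profile(adata, "S-D1", "control")
        p2 = subtype_profile(adata[perm].copy(), "S-D1", "control")
        np.testing.assert_allclose(p1.p, p2.p, atol=1e-12)

    def test_empty_group_errors(self, small_dataset):
        adata, _ = small_dataset
        with pytest.raises(ValueError, match="no cells"):
            subtype_profile(adata, "NOT-A-TYPE", "control")


class TestJsDistance:
    def test_identity_of_indiscernibles(self):
        p = np.array([0.2, 0.3, 0.5])
        assert js_distance(p, p) == 0.0

    def test_disjoint_supports_saturate(self):
        assert js_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_term_by_term_oracle(self):
        # P=(1,0), Q=(.5,.5): JSD = 1/2 KL(P||M) + 1/2 KL(Q||M), M=(.75,.25)
        kl_pm = 1.0 * np.log2(1.0 / 0.75)
        kl_qm = 0.5 * np.log2(0.5 / 0.75) + 0.5 * np.log2(0.5 / 0.25)
        expected = np.sqrt(0.5 * kl_pm + 0.5 * kl_qm)
        assert js_distance([1, 0], [0.5, 0.5]) == pytest.approx(expected,
                                                                abs=1e-12)

    @pytest.mark.parametrize("bad,err", [
        (([0.5, 0.5, 0.0], [0.5, 0.5]), "length"),
        (([1.5, -0.5], [0.5, 0.5]), "non-negative"),
        (([0.4, 0.4], [0.5, 0.5]), "sum to 1"),
    ])
    def test_input_validation(self, bad, err):
        with pytest.raises(ValueError, match=err):
            js_distance(*bad)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10 ** 6))
    def test_metric_properties_and_scipy_agreement(self, seed):
        rng = np.random.default_rng(seed)
        p, q, r = (rng.dirichlet(np.ones(6)) for _ in range(3))
        dpq, dqr, dpr = (js_distance(a, b)
                         for a, b in ((p, q), (q, r), (p, r)))
        assert dpq == pytest.approx(js_distance(q, p), abs=1e-12)  # symmetry
        assert dpr <= dpq + dqr + 1e-12  # triangle inequality
        assert 0.0 <= dpq <= 1.0
        assert dpq == pytest.approx(jensenshannon(p, q, base=2), abs=1e-9)


def _profiles(d):
    return {t: SubtypeProfile(t, "x", np.asarray(p), pd.Index([]), 1)
            for t, p in d.items()}


class TestLoss:
    def test_identical_phenotypes_zero_loss(self):
        ctl = _profiles({"M-D1": [0.5, 0.5], "S-D1": [0.9, 0.1]})
        losses = distance_loss(ctl, ctl)
        assert (losses["loss"] == 0).all()

    def test_loss_arithmetic(self):
        ctl = _profiles({"A-D1": [1.0, 0.0], "B-D1": [0.0, 1.0]})
        cnd = _profiles({"A-D1": [0.8, 0.2], "B-D1": [0.2, 0.8]})
        losses = distance_loss(ctl, cnd)
        d_ctl = js_distance([1, 0], [0, 1])
        d_cnd = js_distance([0.8, 0.2], [0.2, 0.8])
        assert losses.loc[0, "loss"] == pytest.approx(d_cnd - d_ctl)

    def test_unmatched_subtype_skipped_with_warning(self):
        ctl = _profiles({"M-D1": [0.5, 0.5], "S-D1": [0.9, 0.1],
                         "S-D2": [0.2, 0.8]})
        cnd = _profiles({"M-D1": [0.5, 0.5], "S-D1": [0.9, 0.1]})
        with pytest.warns(UserWarning, match="skipped"):
            losses = distance_loss(ctl, cnd)
        assert set(losses["subtype_a"]) | set(losses["subtype_b"]) == {
            "M-D1", "S-D1"}


def test_pair_axis_classification():
    assert pair_axis("S-D1", "M-D1") == "S-M"
    assert pair_axis("M-D2", "O-D2") == "S-M"
    assert pair_axis("S-D1", "S-D2") == "D1-D2"
    assert pair_axis("O-D2", "S-D1") == "D1-D2"
    assert pair_axis("M-D1", "S-D2") == "mixed"


def _loss_frame(rows):
    return pd.DataFrame(rows, columns=["subtype_a", "subtype_b", "d_control",
                                       "d_condition", "loss", "pair_axis"])


def _complete_loss_frame(source, losses_from_source, filler=-0.05):
    """Full pairwise loss table where ``source``'s losses are prescribed."""
    from itertools import combinations

    rows = [(source, t, 0.4, 0.4 + l, l, "x")
            for t, l in losses_from_source.items()]
    others = list(losses_from_source)
    rows += [(a, b, 0.4, 0.4 + filler, filler, "x")
             for a, b in combinations(others, 2)]
    return _loss_frame(rows)


class TestMeanLoss:
    def test_hand_mean(self):
        frame = _complete_loss_frame(
            "S-D2", {"M-D1": -0.1, "S-D1": -0.2, "M-D2": -0.3, "X-D1": -0.4})
        out = per_celltype_mean_loss(frame, exclude=())
        assert out.loc["S-D2", "mean_loss"] == pytest.approx(-0.25)
        assert out.loc["S-D2", "n"] == 4

    def test_exclusion_rule_and_counts(self, small_dataset):
        adata, _ = small_dataset
        from spnblur.identity import subtype_profile
        profs = {ph: {t: subtype_profile(adata, t, ph)
                      for t in ("M-D1", "S-D1", "M-D2", "S-D2", "O-D2")}
                 for ph in ("control", "HD")}
        losses = distance_loss(profs["control"], profs["HD"])
        out = per_celltype_mean_loss(losses, exclude=("O-D2",))
        # O-D2 excluded as target: canonical sources keep 3 pairs, O-D2 all 4
        assert out.loc["M-D1", "n"] == 3
        assert out.loc["O-D2", "n"] == 4

    def test_ci_matches_t_formula(self):
        vals = [-0.1, -0.2, -0.3, -0.4]
        frame = _complete_loss_frame(
            "S-D2", dict(zip(["A-D1", "B-D1", "C-D1", "D-D1"], vals)))
        out = per_celltype_mean_loss(frame, exclude=())
        half = stats.t.ppf(0.975, 3) * np.std(vals, ddof=1) / 2.0
        assert out.loc["S-D2", "ci_high"] - out.loc["S-D2", "mean_loss"] \
            == pytest.approx(half)

    def test_single_pair_errors(self):
        rows = [("A-D1", "B-D1", 0.4, 0.3, -0.1, "x")]
        with pytest.raises(ValueError, match=">= 2"):
            per_celltype_mean_loss(_loss_frame(rows), exclude=())


class TestRegression:
    def _frame(self, x, y):
        rows = [(f"A{i}-D1", f"B{i}-D1", xi, xi + yi, yi, "mixed")
                for i, (xi, yi) in enumerate(zip(x, y))]
        return _loss_frame(rows)

    def test_exact_line_zero_residuals(self):
        x = np.linspace(0.1, 0.9, 8)
        y = -0.2 * x - 0.05
        reg = loss_vs_endogenous_regression(self._frame(x, y), order=1)
        np.testing.assert_allclose(reg.table["fitted"], y, atol=1e-12)
        assert (reg.table["flag"] == "within").all()
        assert reg.r_squared == pytest.approx(1.0)

    def test_exact_quadratic_recovered_at_order_two(self):
        x = np.linspace(0.1, 0.9, 8)
        y = 0.3 * x ** 2 - 0.4 * x + 0.01
        reg = loss_vs_endogenous_regression(self._frame(x, y), order=2)
        np.testing.assert_allclose(reg.table["fitted"], y, atol=1e-10)
        np.testing.assert_allclose(reg.params, [0.01, -0.4, 0.3], atol=1e-8)

    def test_displaced_point_flagged_below(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0.1, 0.9, 20)
        y = -0.2 * x + rng.normal(0, 0.005, 20)
        clean = loss_vs_endogenous_regression(self._frame(x, y), order=1,
                                              ci_level=0.99)
        half = (clean.table.loc[10, "band_high"]
                - clean.table.loc[10, "band_low"]) / 2
        y2 = y.copy()
        y2[10] -= 5 * half
        reg = loss_vs_endogenous_regression(self._frame(x, y2), order=1,
                                            ci_level=0.99)
        assert reg.table.loc[10, "flag"] == "below"

    def test_degenerate_predictor_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            loss_vs_endogenous_regression(self._frame([0.3] * 5,
                                                      [0.1] * 5))


class TestFractions:
    def test_fraction_arithmetic(self):
        counts = {"M-D1": 10, "S-D1": 20, "M-D2": 30, "S-D2": 40}
        rows, samples, phen, subs = [], [], [], []
        for t, n in counts.items():
            for ph in ("control", "HD"):
                for _ in range(n):
                    rows.append([1, 1])
                    samples.append("s1" if ph == "control" else "s2")
                    phen.append(ph)
                    subs.append(t)
        adata = make_adata(rows, samples, phen, subs)
        out = subtype_fractions(adata, universe=list(counts))
        np.testing.assert_allclose(out["fraction_control"],
                                   [0.1, 0.2, 0.3, 0.4])
        np.testing.assert_allclose(out["change"], 0.0, atol=1e-12)

    def test_unknown_label_errors(self, small_dataset):
        adata, _ = small_dataset
        with pytest.raises(ValueError, match="unknown"):
            subtype_fractions(adata, universe=["M-D1", "Z-D9"])

    def test_depletion_shows_most_negative_change(self):
        from spnblur.syndata import SimConfig, generate_dataset
        cfg = SimConfig(n_genes=100, n_samples_per_phenotype=2,
                        cells_per_sample_per_subtype=50,
                        depletion={"S-D2": 0.3}, seed=6)
        adata, _ = generate_dataset(cfg)
        out = subtype_fractions(adata)
        assert out["change"].idxmin() == "S-D2"
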