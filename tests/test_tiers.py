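"""Binding scores, quantile tiers, matched controls and the trend test."""

import numpy as np
import pandas as pd
import pytest

from snhgpipe.differential import DEThresholds
from snhgpipe.quantify import CountsTable
from snhgpipe.tiers import (
    Peak,
    assign_tiers,
    matched_controls,
    rip_enrichment,
    score_binding,
    tier_trend_test,
)


class TestScoreBinding:
    def test_sum_of_signal_times_neglogp(self):
        ev = {"g": [Peak(5, 1e-3), Peak(2, 1e-2)]}
        assert score_binding(ev)["g"] == pytest.approx(19.0)

    def test_no_peaks_scores_zero(self):
        assert score_binding({"g": []})["g"] == 0.0

    def test_neglogp_capped_at_ten(self):
        assert score_binding({"g": [Peak(1, 1e-15)]})["g"] == pytest.approx(
            10.0
        )

    def test_invalid_peaks_rejected(self):
        with pytest.raises(ValueError):
            Peak(-1, 0.5)
        with pytest.raises(ValueError):
            Peak(1, 0.0)


class TestAssignTiers:
    def test_even_split(self):
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        tiers = assign_tiers(scores, k=2)
        assert tiers.tolist() == [1, 1, 2, 2]

    def test_unbound_genes_get_tier_zero(self):
        scores = pd.Series({"a": 0.0, "b": 2.0, "c": 3.0})
        tiers = assign_tiers(scores, k=2)
        assert tiers["a"] == 0 and set(tiers[["b", "c"]]) == {1, 2}

    def test_all_equal_collapse_with_warning(self):
        scores = pd.Series({"a": 2.0, "b": 2.0, "c": 2.0, "d": 2.0})
        with pytest.warns(UserWarning):
            tiers = assign_tiers(scores, k=2)
        assert (tiers == 1).all()

    def test_fewer_bound_than_tiers_reduces_k(self):
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 0.0})
        with pytest.warns(UserWarning):
            tiers = assign_tiers(scores, k=4)
        assert tiers.max() == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_quantile_sizes_balanced(self, seed):
        rng = np.random.default_rng(seed)
        scores = pd.Series(rng.uniform(0.1, 10.0, 101),
                           index=[f"g{i}" for i in range(101)])
        tiers = assign_tiers(scores, k=4)
        sizes = tiers[tiers > 0].value_counts()
        assert sizes.max() - sizes.min() <= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_score(self, seed):
        rng = np.random.default_rng(10 + seed)
        scores = pd.Series(rng.uniform(0.1, 10.0, 60),
                           index=[f"g{i}" for i in range(60)])
        tiers = assign_tiers(scores, k=4)
        bumped = scores.copy()
        gene = scores.index[int(rng.integers(60))]
        bumped[gene] = scores.max() + 1
        tiers2 = assign_tiers(bumped, k=4)
        assert tiers2[gene] >= tiers[gene]


class TestMatchedControls:
    def test_exact_histogram_with_ample_controls(self):
        rng = np.random.default_rng(0)
        n_bound, n_unbound = 40, 400
        tiers = pd.Series([1] * n_bound + [0] * n_unbound,
                          index=[f"g{i}" for i in range(n_bound + n_unbound)])
        expr = pd.Series(rng.uniform(0, 100, n_bound + n_unbound),
                         index=tiers.index)
        controls = matched_controls(tiers, expr, seed=1)
        bins = pd.cut(expr, np.quantile(expr, np.linspace(0, 1, 11)),
                      include_lowest=True)
        target_hist = bins[tiers == 1].value_counts().sort_index()
        control_hist = bins[controls[1]].value_counts().sort_index()
        assert (target_hist == control_hist).all()
        assert len(controls[1]) == n_bound

    def test_seeded_runs_identical(self):
        rng = np.random.default_rng(2)
        tiers = pd.Series(rng.integers(0, 3, 200),
                          index=[f"g{i}" for i in range(200)])
        expr = pd.Series(rng.uniform(0, 50, 200), index=tiers.index)
        a = matched_controls(tiers, expr, seed=7)
        b = matched_controls(tiers, expr, seed=7)
        assert a == b

    def test_expression_matched_when_binding_tracks_expression(self):
        # binding probability grows with expression: naive controls would
        # be lower-expressed; matching should close the gap
        rng = np.random.default_rng(3)
        n = 2000
        expr = pd.Series(rng.lognormal(3, 1, n),
                         index=[f"g{i}" for i in range(n)])
        p_bound = (expr.rank(pct=True) * 0.5).values
        tiers = pd.Series((rng.random(n) < p_bound).astype(int),
                          index=expr.index)
        controls = matched_controls(tiers, expr, seed=4)
        target_median = expr[tiers == 1].median()
        control_median = expr[controls[1]].median()
        assert abs(control_median - target_median) / target_median < 0.05


class TestTierTrend:
    def make_de(self, log2fcs, index):
        return pd.DataFrame(
            {"baseMean": 100.0, "log2FC": log2fcs, "pvalue": 0.5,
             "padj": 0.5, "call": "ns"},
            index=index,
        )

    def test_planted_monotone_effect_detected(self):
        rng = np.random.default_rng(5)
        n = 400
        tiers = pd.Series(rng.integers(0, 5, n),
                          index=[f"g{i}" for i in range(n)])
        lfc = rng.normal(-0.2 * tiers.values, 0.3)
        out = tier_trend_test(tiers, self.make_de(lfc, tiers.index))
        assert out["spearman_rho"] < 0
        assert out["spearman_p"] < 0.01
        assert all(v["p"] < 0.05 for t, v in out["vs_tier0"].items()
                   if t >= 3)

    def test_shuffled_tiers_show_no_trend(self):
        rng = np.random.default_rng(6)
        n = 400
        tiers = pd.Series(rng.integers(0, 5, n),
                          index=[f"g{i}" for i in range(n)])
        lfc = rng.normal(0, 0.3, n)
        out = tier_trend_test(tiers, self.make_de(lfc, tiers.index))
        assert abs(out["spearman_rho"]) < 0.15

    def test_two_tiers_reduce_to_two_sample_case(self):
        rng = np.random.default_rng(7)
        tiers = pd.Series([0] * 30 + [1] * 30,
                          index=[f"g{i}" for i in range(60)])
        lfc = np.concatenate([rng.normal(0, 0.1, 30),
                              rng.normal(-1, 0.1, 30)])
        out = tier_trend_test(tiers, self.make_de(lfc, tiers.index))
        assert out["vs_tier0"][1]["p"] < 1e-6

    def test_single_tier_is_error(self):
        tiers = pd.Series([1] * 10, index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            tier_trend_test(tiers, self.make_de(np.zeros(10), tiers.index))


class TestRIPEnrichment:
    def test_gates_applied(self):
        rng = np.random.default_rng(8)
        idx = [f"g{i}" for i in range(30)]
        base = rng.poisson(100, (30, 3))
        ip = base.copy()
        ip[0] *= 4        # strongly enriched
        ip[1] = base[1]   # unchanged
        counts = pd.DataFrame(
            np.hstack([base, ip]),
            columns=["in1", "in2", "in3", "ip1", "ip2", "ip3"],
            index=idx,
        )
        cond = pd.Series(["input"] * 3 + ["ip"] * 3,
                         index=counts.columns)
        table = CountsTable(counts, cond)
        enriched, de = rip_enrichment(table, "input", "ip",
                                      DEThresholds(min_mean_count=1))
        assert "g0" in enriched
        assert "g1" not in enriched
        assert enriched == set(de.index[de["call"] == "up"])
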