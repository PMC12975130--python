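"""TAD zoning, cis-enrichment and contact-interval tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snhgpipe.zones import (
    TADMap,
    assign_zones,
    contact_interval_test,
    digital_cis_test,
    zone_effect_test,
)


@pytest.fixture
def tadmap():
    return TADMap(
        "chrA", ((0, 1_000_000), (1_000_000, 2_000_000),
                 (2_000_000, 8_000_000)),
        1_000_000, "FOCAL",
    )


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "tss"],
                        index=[f"g{i}" for i in range(len(rows))])


class TestTADMap:
    def test_boundary_must_be_shared_edge(self):
        with pytest.raises(ValueError):
            TADMap("c", ((0, 10), (10, 20)), 5, "f")

    def test_overlapping_tads_rejected(self):
        with pytest.raises(ValueError):
            TADMap("c", ((0, 12), (10, 20)), 10, "f")


class TestAssignZones:
    def test_three_zones(self, tadmap):
        genes = gene_frame(
            [("chrA", 500_000), ("chrA", 5_000_000), ("chrB", 100_000)]
        )
        zones = assign_zones(genes, tadmap)
        assert zones.loc["g0", "zone"] == "Cis"
        assert zones.loc["g1", "zone"] == "SameChromosome"
        assert zones.loc["g2", "zone"] == "Trans"

    def test_focal_locus_excluded_and_missing_tss_skipped(self, tadmap):
        genes = pd.DataFrame(
            {"chrom": ["chrA", "chrA"], "tss": [500_000, np.nan]},
            index=["FOCAL", "g1"],
        )
        zones = assign_zones(genes, tadmap)
        assert "FOCAL" not in zones.index
        assert zones.attrs["skipped"] == ["g1"]

    def test_every_gene_gets_exactly_one_zone(self, tadmap):
        rng = np.random.default_rng(0)
        genes = gene_frame(
            [("chrA" if rng.random() < 0.7 else "chrB",
              int(rng.integers(0, 8_000_000))) for _ in range(200)]
        )
        zones = assign_zones(genes, tadmap)
        assert len(zones) == 200
        assert zones["zone"].isin(["Cis", "SameChromosome", "Trans"]).all()


def make_de(log2fcs, calls=None):
    n = len(log2fcs)
    return pd.DataFrame(
        {
            "baseMean": 100.0,
            "log2FC": log2fcs,
            "pvalue": 0.5,
            "padj": 0.5,
            "call": calls if calls is not None else ["ns"] * n,
        },
        index=[f"g{i}" for i in range(n)],
    )


class TestZoneEffect:
    def test_all_one_zone_is_error(self, tadmap):
        de = make_de([0.1] * 10)
        zones = pd.DataFrame({"zone": ["Trans"] * 10}, index=de.index)
        with pytest.raises(ValueError):
            zone_effect_test(de, zones)

    def test_small_zone_excluded(self, tadmap):
        rng = np.random.default_rng(1)
        de = make_de(rng.normal(0, 0.1, 43))
        zones = pd.DataFrame(
            {"zone": ["Cis"] * 3 + ["SameChromosome"] * 20 + ["Trans"] * 20},
            index=de.index,
        )
        out = zone_effect_test(de, zones)
        assert out["excluded_zones"] == ["Cis"]
        assert set(out["classes"]) == {"SameChromosome", "Trans"}


class TestDigitalCis:
    def fisher_enum(self, table):
        """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
        (a, b), (c, d) = table
        n = a + b + c + d
        row1, col1 = a + b, a + c
        p_obs = stats.hypergeom.pmf(a, n, col1, row1)
        total = 0.0
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
            pk = stats.hypergeom.pmf(k, n, col1, row1)
            if pk <= p_obs * (1 + 1e-9):
                total += pk
        return total

    def test_fisher_matches_enumeration(self):
        de = make_de(
            [0.0] * 110,
            calls=["up"] * 8 + ["ns"] * 10 + ["up"] * 2 + ["ns"] * 90,
        )
        zones = pd.DataFrame(
            {"zone": ["Cis"] * 18 + ["Trans"] * 92}, index=de.index
        )
        out = digital_cis_test(de, zones, "up")
        assert out["table"] == [[8, 2], [10, 90]]
        assert out["p"] == pytest.approx(self.fisher_enum([[8, 2], [10, 90]]),
                                         rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_fisher_matches_enumeration_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n_cis, n_other = int(rng.integers(5, 60)), int(rng.integers(20, 140))
        calls = (["up" if rng.random() < 0.2 else "ns"
                  for _ in range(n_cis + n_other)])
        if "up" not in calls:
            calls[0] = "up"
        de = make_de([0.0] * (n_cis + n_other), calls=calls)
        zones = pd.DataFrame(
            {"zone": ["Cis"] * n_cis + ["Trans"] * n_other}, index=de.index
        )
        out = digital_cis_test(de, zones, "up")
        assert out["p"] == pytest.approx(self.fisher_enum(out["table"]),
                                         rel=1e-9)

    def test_uniform_proportions_null(self):
        rng = np.random.default_rng(42)
        ors, ps = [], []
        for _ in range(50):
            calls = ["up" if rng.random() < 0.1 else "ns"
                     for _ in range(300)]
            if "up" not in calls:
                calls[0] = "up"
            de = make_de([0.0] * 300, calls=calls)
            zones = pd.DataFrame(
                {"zone": ["Cis"] * 60 + ["Trans"] * 240}, index=de.index
            )
            out = digital_cis_test(de, zones, "up")
            ors.append(out["odds_ratio"])
            ps.append(out["p"])
        assert np.median(ors) == pytest.approx(1.0, abs=0.35)
        assert np.mean(np.array(ps) < 0.05) <= 0.1

    def test_no_significant_genes_is_error(self):
        de = make_de([0.0] * 10)
        zones = pd.DataFrame(
            {"zone": ["Cis"] * 5 + ["Trans"] * 5}, index=de.index
        )
        with pytest.raises(ValueError):
            digital_cis_test(de, zones, "up")

    def test_empty_cis_zone_is_error(self):
        de = make_de([0.0] * 10, calls=["up"] + ["ns"] * 9)
        zones = pd.DataFrame({"zone": ["Trans"] * 10}, index=de.index)
        with pytest.raises(ValueError):
            digital_cis_test(de, zones, "up")


class TestContactInterval:
    def test_hand_computed_chi_squared(self):
        out = contact_interval_test((10, 30), (100, 100))
        assert out["chi2"] == pytest.approx(12.5)
        assert out["p"] == pytest.approx(4.07e-4, rel=0.01)

    def test_identical_conditions_chi2_zero(self):
        out = contact_interval_test((10, 10), (100, 100))
        assert out["chi2"] == 0.0 and out["p"] == 1.0

    def test_degenerate_margin_warns(self):
        out = contact_interval_test((0, 0), (100, 100))
        assert out["chi2"] == 0.0
        assert "warning" in out

    def test_symmetric_in_condition_order(self):
        a = contact_interval_test((17, 45), (200, 180))
        b = contact_interval_test((45, 17), (180, 200))
        assert a["chi2"] == pytest.approx(b["chi2"])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            contact_interval_test((10, 120), (100, 100))
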