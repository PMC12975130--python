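"""The synthetic-data generators: determinism, contracts, calibration."""

import math

import numpy as np
import pytest
from scipy import stats

from snhgpipe.differential import de_test
from snhgpipe.metrics import nuclear_kurtosis
from snhgpipe.simulate import (
    SimConfig,
    gen_annotation,
    gen_counts,
    gen_label_timecourse,
    gen_nuclear_pixels,
)


class TestConfigValidation:
    def test_bad_replicates(self):
        with pytest.raises(ValueError):
            SimConfig(n_replicates=1)

    def test_bad_dispersion(self):
        with pytest.raises(ValueError):
            SimConfig(nb_dispersion=-0.1)

    def test_nonfinite_effect(self):
        with pytest.raises(ValueError):
            SimConfig(effects={"zone:Cis": float("nan")})


class TestGenAnnotation:
    def test_no_snhgs_empty_sno_records(self):
        ann = gen_annotation(SimConfig(seed=1, n_genes=30, n_snhgs=0))
        assert ann.snos == []
        assert len(ann.genes) == 31  # includes the focal lncRNA

    def test_generator_respects_partition_contract(self, small_annotation):
        parts, diagnostics = small_annotation.partitions()
        assert diagnostics == []
        hosts = {s.host_id for s in small_annotation.snos}
        assert len(parts) == len(hosts)

    def test_deterministic_under_fixed_seed(self, small_cfg):
        a = gen_annotation(small_cfg)
        b = gen_annotation(small_cfg)
        assert [g for g in a.genes] == [g for g in b.genes]
        assert a.snos == b.snos
        assert a.tads == b.tads

    def test_focal_locus_abuts_tad_boundary(self, small_annotation):
        ann = small_annotation
        focal = next(g for g in ann.genes if g.gene_id == "LNC_FOCAL")
        assert focal.span[0] == ann.focal_tads.focal_boundary
        left, right = ann.focal_tads.flanking_tads
        assert left[1] == right[0] == ann.focal_tads.focal_boundary

    def test_genes_on_multiple_chromosomes(self, small_annotation):
        assert len({g.chrom for g in small_annotation.genes}) >= 2

    def test_snos_strictly_inside_introns(self, small_annotation):
        by_id = {g.gene_id: g for g in small_annotation.genes}
        for sno in small_annotation.snos:
            host = by_id[sno.host_id]
            lo, hi = host.span
            assert lo < sno.start and sno.end < hi
            for s, e in host.exon_union():
                assert not (sno.start < e and s < sno.end)

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ValueError, match="infeasible|at least"):
            gen_annotation(SimConfig(seed=1, n_genes=2, n_snhgs=0))


class TestGenCounts:
    def test_deterministic_under_fixed_seed(self, small_cfg,
                                            small_annotation):
        g1, r1, _ = gen_counts(small_cfg, small_annotation)
        g2, r2, _ = gen_counts(small_cfg, small_annotation)
        assert g1.counts.equals(g2.counts)
        assert r1.counts.equals(r2.counts)

    def test_library_size_within_twofold(self, small_cfg, small_annotation):
        table, _, _ = gen_counts(small_cfg, small_annotation)
        sums = table.counts.sum(axis=0)
        assert ((sums > small_cfg.library_size / 2)
                & (sums < small_cfg.library_size * 2)).all()

    def test_null_log2fc_centered_at_zero(self):
        cfg = SimConfig(seed=1, n_genes=500, n_snhgs=25)
        ann = gen_annotation(cfg)
        table, _, _ = gen_counts(cfg, ann)
        de = de_test(table, "ctrl", "kd")
        tested = de[de["call"] != "filtered"]
        assert abs(tested["log2FC"].mean()) < 0.05

    def test_poisson_limit_effect_doubles_snorna_regions(self):
        # dispersion -> 0 plus a +1 log2 offset: law of large numbers at
        # high depth pins the KD/ctrl mean ratio at 2
        cfg = SimConfig(seed=1, n_genes=60, n_snhgs=40, nb_dispersion=0.0,
                        effects={"region:Snorna": 1.0},
                        library_size=10_000_000)
        ann = gen_annotation(cfg)
        _, regions, truth = gen_counts(cfg, ann)
        sno = truth.region_truth["region_class"] == "Snorna"
        ctrl = regions.counts.loc[sno, regions.samples_for("ctrl")]
        kd = regions.counts.loc[sno, regions.samples_for("kd")]
        ratio = kd.values.mean() / ctrl.values.mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_every_feature_has_ground_truth(self, small_cfg,
                                            small_annotation):
        table, regions, truth = gen_counts(small_cfg, small_annotation)
        assert set(table.counts.index) == set(truth.gene_truth.index)
        assert set(regions.counts.index) == set(truth.region_truth.index)


class TestGenLabelTimecourse:
    def test_closed_form_fraction_at_halflife(self):
        tc = gen_label_timecourse(SimConfig(seed=0), sigma=5.0,
                                  delta=math.log(2) / 4, depth=math.inf)
        assert tc.new[0] == 0.0
        assert tc.new[1] / tc.total[1] == pytest.approx(0.5)

    def test_zero_new_at_time_zero_with_noise(self):
        tc = gen_label_timecourse(SimConfig(seed=5), sigma=5.0, delta=0.3,
                                  depth=500.0)
        assert tc.new[0] == 0.0

    def test_binomial_mc_mean_fraction(self):
        rng = np.random.default_rng(1)
        cfg = SimConfig(seed=1)
        fracs = []
        for _ in range(10_000):
            tc = gen_label_timecourse(cfg, sigma=1.0, delta=0.1,
                                      times=(0, 8), depth=200.0, rng=rng)
            if tc.total[1] > 0:
                fracs.append(tc.new[1] / tc.total[1])
        expected = 1 - math.exp(-0.8)
        # binomial MC error at depth 200 over 1e4 draws
        assert np.mean(fracs) == pytest.approx(expected, abs=0.002)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            gen_label_timecourse(SimConfig(seed=0), 1.0, 0.0)


class TestGenNuclearPixels:
    def test_zero_weight_log_intensities_are_gaussian(self):
        px, _ = gen_nuclear_pixels(SimConfig(seed=3), n_nuclei=1,
                                   n_pixels=100_000, mixture_weight=0.0)
        g2 = nuclear_kurtosis(np.log(px["intensity"].values))
        assert abs(g2) < 0.05

    def test_mixture_raises_per_nucleus_kurtosis(self):
        base, _ = gen_nuclear_pixels(SimConfig(seed=4), n_nuclei=50,
                                     mixture_weight=0.0)
        mixed, _ = gen_nuclear_pixels(SimConfig(seed=4), n_nuclei=50,
                                      mixture_weight=0.2)
        med = {
            key: np.median([
                nuclear_kurtosis(g["intensity"].values)
                for _, g in df.groupby("nucleus")
            ])
            for key, df in (("base", base), ("mixed", mixed))
        }
        assert med["mixed"] > med["base"]

    def test_deterministic_and_weight_validated(self):
        a, _ = gen_nuclear_pixels(SimConfig(seed=5), n_nuclei=3,
                                  mixture_weight=0.1)
        b, _ = gen_nuclear_pixels(SimConfig(seed=5), n_nuclei=3,
                                  mixture_weight=0.1)
        assert a.equals(b)
        with pytest.raises(ValueError):
            gen_nuclear_pixels(SimConfig(seed=5), mixture_weight=1.5)


class TestEffectRecoveryCalibration:
    """Seeded power/calibration checks for the planted-effect channels."""

    def test_zone_effect_power(self):
        from snhgpipe.differential import group_shift

        cfg0 = SimConfig(seed=1, n_genes=200, n_snhgs=10,
                         effects={"zone:Cis": -0.5})
        ann = gen_annotation(cfg0)
        hits = 0
        n_runs = 20
        for s in range(n_runs):
            cfg = SimConfig(seed=1000 + s, n_genes=200, n_snhgs=10,
                            effects={"zone:Cis": -0.5})
            table, _, truth = gen_counts(cfg, ann)
            de = de_test(table, "ctrl", "kd")
            merged = de.join(truth.gene_truth["zone"])
            merged = merged[merged["call"] != "filtered"]
            sub = merged[merged["zone"].isin(["Cis", "Trans"])]
            out = group_shift(sub["log2FC"].values, sub["zone"].values)
            if out["pairwise"][("Cis", "Trans")]["p"] < 0.01:
                hits += 1
        assert hits >= int(0.95 * n_runs)

    def test_null_false_positive_rate(self):
        cfg0 = SimConfig(seed=2, n_genes=300, n_snhgs=15)
        ann = gen_annotation(cfg0)
        fps, total = 0, 0
        for s in range(20):
            cfg = SimConfig(seed=2000 + s, n_genes=300, n_snhgs=15)
            table, _, _ = gen_counts(cfg, ann)
            de = de_test(table, "ctrl", "kd")
            tested = de[de["call"] != "filtered"]
            fps += int((tested["padj"] < 0.05).sum())
            total += len(tested)
        assert fps / total <= 0.05
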