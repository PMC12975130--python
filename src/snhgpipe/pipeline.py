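"""End-to-end orchestration of the synthetic analysis pipeline.

Each stage reads its inputs, writes its artifact plus a JSON summary under
the configured output directory, and the final report aggregates the key
statistics.  Stages are runnable individually but check that their
dependencies have run; identical configuration and seed give identical
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .differential import DEThresholds, de_test, group_shift
from .kinetics import compare_kinetics, fit_kinetics
from .metrics import migration_rate, nuclear_kurtosis, wound_closure
from .quantify import fpkm, size_factors
from .screen import rank_candidates, run_screen
from .simulate import (
    Annotation,
    SimConfig,
    gen_annotation,
    gen_counts,
    gen_nuclear_pixels,
    gen_peaks,
    gen_screen_inputs,
    gen_timecourse_cohort,
)
from .tiers import assign_tiers, matched_controls, score_binding, tier_trend_test
from .zones import assign_zones, contact_interval_test, digital_cis_test, zone_effect_test

REPORT_SCHEMA_VERSION = 1

STAGES = ("simulate", "partition", "quantify", "de", "zones", "screen",
          "tiers", "kinetics", "metrics", "report")

_DEPS = {
    "simulate": (),
    "partition": ("simulate",),
    "quantify": ("simulate", "partition"),
    "de": ("quantify",),
    "zones": ("de",),
    "screen": ("simulate",),
    "tiers": ("de",),
    "kinetics": ("simulate",),
    "metrics": ("simulate",),
    "report": (),
}


@dataclass
class PipelineConfig:
    outdir: Path
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    screen_min_confidence: float = 1.0
    tier_k: int = 4
    kinetics_n_features: int = 100
    kinetics_depth: float = 500.0
    verbosity: int = 1

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)


class DependencyError(RuntimeError):
    pass


class _Context:
    """In-memory stage products for one pipeline run."""

    def __init__(self) -> None:
        self.annotation: Annotation | None = None
        self.products: dict = {}


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Run the requested stages in order and return the aggregated report.

    ``stages`` defaults to the full pipeline.  A stage whose dependency is
    not in the requested set raises :class:`DependencyError` naming the
    missing prior stage.
    """
    requested = list(stages) if stages is not None else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    done = set()
    for st in STAGES:
        if st not in requested:
            continue
        for dep in _DEPS[st]:
            if dep not in done:
                raise DependencyError(
                    f"stage '{st}' requires stage '{dep}' to run first"
                )
        done.add(st)

    cfg.outdir.mkdir(parents=True, exist_ok=True)
    ctx = _Context()
    summaries: dict = {}
    runners = {
        "simulate": _stage_simulate, "partition": _stage_partition,
        "quantify": _stage_quantify, "de": _stage_de, "zones": _stage_zones,
        "screen": _stage_screen, "tiers": _stage_tiers,
        "kinetics": _stage_kinetics, "metrics": _stage_metrics,
    }
    for st in STAGES:
        if st not in requested or st == "report":
            continue
        summaries[st] = runners[st](cfg, ctx)
        sio.write_json(summaries[st], cfg.outdir / f"{st}.summary.json")
    report = write_report(summaries, cfg.outdir / "report.json")
    return report


def write_report(stage_summaries: dict, path) -> dict:
    """Aggregate stage summaries into a schema-versioned report JSON."""
    if not stage_summaries:
        raise ValueError("need at least one stage output to report")
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "stages": {st: stage_summaries.get(st) for st in STAGES
                   if st != "report"},
    }
    sio.write_json(report, path)
    return report


def render_report(report: dict) -> str:
    """Human-readable summary from the report JSON."""
    lines = [f"snhgpipe report (schema v{report['schema_version']})"]
    for st, summary in report["stages"].items():
        if summary is None:
            continue
        lines.append(f"[{st}]")
        for k, v in sorted(summary.items()):
            if isinstance(v, (int, float, str)):
                lines.append(f"  {k}: {v}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig, ctx: _Context) -> dict:
    ann = gen_annotation(cfg.sim)
    ctx.annotation = ann
    gene_table, region_table, truth = gen_counts(cfg.sim, ann)
    ctx.products.update(gene_table=gene_table, region_table=region_table,
                        truth=truth)
    paths = sio.write_annotation(ann.genes, ann.snos, ann.tads,
                                 cfg.outdir / "annotation")
    sio.write_counts(gene_table, cfg.outdir / "gene_counts.tsv")
    sio.write_counts(region_table, cfg.outdir / "region_counts.tsv")
    truth.gene_truth.to_csv(cfg.outdir / "gene_truth.tsv", sep="\t")
    return {
        "n_genes": len(ann.genes), "n_snos": len(ann.snos),
        "n_chromosomes": len(ann.chrom_lengths),
        "focal_boundary": ann.focal_tads.focal_boundary,
        "files": sorted(Path(p).name for p in paths.values()),
    }


def _stage_partition(cfg: PipelineConfig, ctx: _Context) -> dict:
    parts, diagnostics = ctx.annotation.partitions()
    ctx.products["partitions"] = parts
    sio.write_partitions(parts, cfg.outdir / "partitions.bed",
                         cfg.outdir / "partitions.tsv")
    return {"n_partitions": len(parts), "diagnostics": diagnostics}


def _stage_quantify(cfg: PipelineConfig, ctx: _Context) -> dict:
    region_table = ctx.products["region_table"]
    factors = size_factors(region_table.counts)
    fp = fpkm(region_table.counts, region_table.lengths)
    fp.to_csv(cfg.outdir / "region_fpkm.tsv", sep="\t")
    return {
        "size_factors": factors.round(4).to_dict(),
        "n_regions": int(len(region_table.counts)),
    }


def _stage_de(cfg: PipelineConfig, ctx: _Context) -> dict:
    out = {}
    for level in ("gene", "region"):
        table = ctx.products[f"{level}_table"]
        de = de_test(table, control="ctrl", treated="kd",
                     thresholds=cfg.thresholds)
        ctx.products[f"{level}_de"] = de
        de.to_csv(cfg.outdir / f"de_{level}.tsv", sep="\t")
        calls = de["call"].value_counts().to_dict()
        out[level] = {c: int(calls.get(c, 0))
                      for c in ("up", "down", "ns", "filtered")}
    region_truth = ctx.products["truth"].region_truth
    labels = region_truth["region_class"].reindex(
        ctx.products["region_de"].index
    )
    shift = group_shift(ctx.products["region_de"]["log2FC"].values,
                        labels.values)
    out["region_class_shift"] = {
        "anova_p": shift["anova_p"],
        "medians": shift["medians"],
    }
    return out


def _stage_zones(cfg: PipelineConfig, ctx: _Context) -> dict:
    ann = ctx.annotation
    zones = assign_zones(ann.gene_info, ann.focal_tads)
    zones.to_csv(cfg.outdir / "zones.tsv", sep="\t")
    de = ctx.products["gene_de"]
    effect = zone_effect_test(de, zones)
    out = {
        "zone_counts": zones["zone"].value_counts().to_dict(),
        "zone_medians": effect["medians"],
        "zone_anova_p": effect["anova_p"],
    }
    for direction in ("up", "down"):
        try:
            out[f"digital_cis_{direction}"] = digital_cis_test(
                de, zones, direction
            )
        except ValueError as exc:
            out[f"digital_cis_{direction}"] = {"error": str(exc)}
    # 4C-style interval comparison on simulated UMI counts: planted drop of
    # in-interval contacts in the knockdown
    rng = np.random.default_rng([cfg.sim.seed, 40])
    ctrl_in = int(rng.binomial(4000, 0.30))
    kd_in = int(rng.binomial(4000, 0.22))
    out["contact_interval"] = contact_interval_test(
        (ctrl_in, kd_in), (4000, 4000)
    )
    return out


def _stage_screen(cfg: PipelineConfig, ctx: _Context) -> dict:
    lncs, elements, de_tables, true_pairs = gen_screen_inputs(
        cfg.sim, ctx.annotation
    )
    candidates = run_screen(lncs, elements, de_tables,
                            min_confidence=cfg.screen_min_confidence)
    ranked = rank_candidates(candidates, de_tables) if candidates else []
    found = {(c.lnc_id, c.target_id) for c in candidates}
    truth = set(true_pairs)
    pd.DataFrame(
        [{"lnc": c.lnc_id, "element": c.element_id, "target": c.target_id,
          "n_conditions": len(c.conditions), "concordant": c.concordant}
         for c in ranked]
    ).to_csv(cfg.outdir / "screen_candidates.tsv", sep="\t", index=False)
    return {
        "n_candidates": len(candidates),
        "n_true_pairs": len(truth),
        "precision": len(found & truth) / len(found) if found else None,
        "recall": len(found & truth) / len(truth) if truth else None,
    }


def _stage_tiers(cfg: PipelineConfig, ctx: _Context) -> dict:
    ann = ctx.annotation
    evidence = gen_peaks(cfg.sim, ann)
    scores = score_binding(evidence)
    tiers = assign_tiers(scores, k=cfg.tier_k)
    tiers.to_frame().to_csv(cfg.outdir / "tiers.tsv", sep="\t")
    de = ctx.products["gene_de"]
    expression = de["baseMean"].reindex(tiers.index).fillna(0.0)
    controls = matched_controls(tiers, expression, seed=cfg.sim.seed)
    trend = tier_trend_test(tiers, de)
    return {
        "tier_sizes": {int(k): int(v)
                       for k, v in tiers.value_counts().sort_index().items()},
        "spearman_rho": trend["spearman_rho"],
        "spearman_p": trend["spearman_p"],
        "n_control_sets": len(controls),
    }


def _stage_kinetics(cfg: PipelineConfig, ctx: _Context) -> dict:
    courses_ctrl, truth = gen_timecourse_cohort(
        cfg.sim, n_features=cfg.kinetics_n_features,
        depth=cfg.kinetics_depth,
    )
    # knockdown: halve the synthesis rate of the first half of the cohort;
    # totals scale with abundance relative to the control steady state
    from .simulate import gen_label_timecourse

    rng = np.random.default_rng([cfg.sim.seed, 41])
    classes = {}
    courses_kd = []
    for i, (fid, row) in enumerate(truth.iterrows()):
        affected = i < len(truth) // 2
        classes[fid] = "affected" if affected else "unaffected"
        sigma = row["sigma"] * (0.5 if affected else 1.0)
        courses_kd.append(
            gen_label_timecourse(cfg.sim, sigma, row["delta"],
                                 depth=cfg.kinetics_depth, feature_id=fid,
                                 condition="kd", rng=rng,
                                 reference_abundance=row["sigma"]
                                 / row["delta"])
        )
    fits_ctrl = {c.feature_id: fit_kinetics(c) for c in courses_ctrl}
    fits_kd = {c.feature_id: fit_kinetics(c, steady_state=False)
               for c in courses_kd}
    table, tests = compare_kinetics(fits_ctrl, fits_kd, classes)
    table.to_csv(cfg.outdir / "kinetics_compare.tsv", sep="\t")
    err = np.abs(
        np.log2([fits_ctrl[f].half_life for f in truth.index])
        - np.log2(truth["halflife"].values)
    )
    rel_err = np.abs(
        np.array([fits_ctrl[f].half_life for f in truth.index])
        / truth["halflife"].values - 1.0
    )
    return {
        "n_features": int(len(truth)),
        "median_rel_halflife_error": float(np.median(rel_err)),
        "median_abs_log2_halflife_error": float(np.median(err)),
        "affected_vs_unaffected_p":
            tests["pairwise"][("affected", "unaffected")]["p"]
            if tests else None,
        "median_dlog2_sigma_affected": float(
            table.loc[[f for f, c in classes.items() if c == "affected"],
                      "dlog2_sigma"].median()
        ),
    }


def _stage_metrics(cfg: PipelineConfig, ctx: _Context) -> dict:
    base_pixels, _ = gen_nuclear_pixels(cfg.sim, n_nuclei=30,
                                        mixture_weight=0.0)
    stress_cfg = SimConfig(seed=cfg.sim.seed + 7)
    stress_pixels, _ = gen_nuclear_pixels(stress_cfg, n_nuclei=30,
                                          mixture_weight=0.2)
    kurt = {
        label: [
            nuclear_kurtosis(grp["intensity"].values)
            for _, grp in df.groupby("nucleus")
        ]
        for label, df in (("ctrl", base_pixels), ("stress", stress_pixels))
    }
    wound = wound_closure(1000.0, 250.0)
    return {
        "median_kurtosis_ctrl": float(np.median(kurt["ctrl"])),
        "median_kurtosis_stress": float(np.median(kurt["stress"])),
        "migration_rate_example": migration_rate(100.0, 60.0, 8.0),
        "wound_closure_pct_example": wound["closure_pct"],
    }
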