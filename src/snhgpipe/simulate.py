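"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study design this pipeline targets: a knockdown
versus control comparison with three biological replicates, a genome of a
few chromosomes carrying snoRNA host genes (SNHGs) whose introns embed
snoRNAs, a focal lncRNA sitting exactly at the shared boundary of two
TADs, negative-binomial RNA-seq counts with planted log2 fold-change
effects on chosen channels (gene class, positional zone, SNHG region
class, binding tier), continuous-labeling new/total time courses with
known synthesis and decay rates, and mixture-model nuclear pixel
intensities with a known high-intensity component weight.

Everything is deterministic under a fixed seed; each generator draws from
its own seeded substream so stages can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import LabelTimeCourse
from .partition import GeneModel, SnoRecord, SNHGPartition, partition_all
from .quantify import CountsTable, ReadInterval
from .tiers import Peak
from .zones import TADMap, assign_zones

FOCAL_ID = "LNC_FOCAL"

#: substream tags so each generator has an independent, reproducible stream
_STREAMS = {"annotation": 1, "counts": 2, "timecourse": 3, "pixels": 4,
            "reads": 5, "peaks": 6}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 500
    n_snhgs: int = 20
    nb_dispersion: float = 0.05
    effects: dict = field(default_factory=dict)
    n_replicates: int = 3
    library_size: int = 2_000_000
    n_chromosomes: int = 3
    histone_fraction: float = 0.05
    bound_fraction: float = 0.3
    n_tiers: int = 4

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.nb_dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        if self.n_genes < self.n_snhgs or self.n_snhgs < 0:
            raise ValueError("need 0 <= n_snhgs <= n_genes")
        if self.n_chromosomes < 2:
            raise ValueError("need >= 2 chromosomes")
        for name, off in self.effects.items():
            if not math.isfinite(off):
                raise ValueError(f"effect {name!r} is not finite")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class Annotation:
    """Generated gene models, snoRNAs, TAD structure and gene metadata."""

    genes: list[GeneModel]
    snos: list[SnoRecord]
    tads: dict                      # chrom -> list of (start, end)
    focal_tads: TADMap
    gene_info: pd.DataFrame         # chrom, tss, strand, class, zone, tier
    chrom_lengths: dict

    def partitions(self) -> tuple[list[SNHGPartition], list[str]]:
        return partition_all(self.genes, self.snos)


@dataclass
class GroundTruth:
    gene_truth: pd.DataFrame        # true_l2fc per gene + metadata
    region_truth: pd.DataFrame | None = None
    kinetics_truth: pd.DataFrame | None = None
    pixel_truth: pd.DataFrame | None = None
    screen_pairs: list | None = None


# ---------------------------------------------------------------------------
# annotation geometry

_GAP_MIN, _GAP_MAX = 8_000, 20_000
_SNO_LEN = 130


def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str,
               start: int, is_snhg: bool) -> tuple[GeneModel, list[SnoRecord]]:
    n_exons = int(rng.integers(2, 5)) if is_snhg else int(rng.integers(1, 5))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = start
    intron_spans = []
    for i in range(n_exons):
        exon_len = int(rng.integers(200, 1000))
        exons.append((pos, pos + exon_len))
        pos += exon_len
        if i < n_exons - 1:
            intron_len = int(rng.integers(500, 3000))
            intron_spans.append((pos, pos + intron_len))
            pos += intron_len
    snos: list[SnoRecord] = []
    if is_snhg:
        k = int(rng.integers(1, min(3, len(intron_spans)) + 1))
        chosen = rng.choice(len(intron_spans), size=k, replace=False)
        for j, idx in enumerate(sorted(chosen)):
            lo, hi = intron_spans[idx]
            margin = 20
            s = int(rng.integers(lo + margin, hi - margin - _SNO_LEN))
            cls = rng.choice(["C/D", "H/ACA", "scaRNA"])
            snos.append(SnoRecord(f"SNO_{gene_id}_{j}", gene_id,
                                  s, s + _SNO_LEN, str(cls)))
    model = GeneModel(gene_id, chrom, strand, (tuple(exons),))
    return model, snos


def gen_annotation(cfg: SimConfig) -> Annotation:
    """Generate gene models, snoRNAs, TADs and the focal boundary lncRNA.

    Genes are laid out sequentially with intergenic gaps across the
    configured chromosomes; every snoRNA sits strictly inside an intron of
    its host; TAD boundaries fall in intergenic gaps, and the focal lncRNA
    starts exactly at one boundary on the first chromosome.
    """
    rng = cfg.rng("annotation")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    per_chrom = np.array_split(np.arange(cfg.n_genes), cfg.n_chromosomes)
    if cfg.n_snhgs > 0:
        snhg_idx = set(
            rng.choice(cfg.n_genes, size=cfg.n_snhgs, replace=False).tolist()
        )
    else:
        snhg_idx = set()

    genes: list[GeneModel] = []
    snos: list[SnoRecord] = []
    info_rows = {}
    tads: dict[str, list[tuple[int, int]]] = {}
    chrom_lengths: dict[str, int] = {}
    focal_boundary = None

    for ci, (chrom, idxs) in enumerate(zip(chroms, per_chrom)):
        pos = int(rng.integers(10_000, 30_000))
        gap_mids = []
        for gi in idxs:
            is_snhg = int(gi) in snhg_idx
            gene_id = f"G{int(gi):04d}"
            model, g_snos = _make_gene(rng, gene_id, chrom, pos, is_snhg)
            genes.append(model)
            snos.extend(g_snos)
            cls = "snhg" if is_snhg else (
                "histone" if rng.random() < cfg.histone_fraction else "regular"
            )
            info_rows[gene_id] = {
                "chrom": chrom, "tss": model.tss, "strand": model.strand,
                "class": cls,
            }
            pos = model.span[1]
            gap = int(rng.integers(_GAP_MIN, _GAP_MAX))
            gap_mids.append(pos + gap // 2)
            pos += gap
        length = pos + 10_000
        chrom_lengths[chrom] = length
        # ~4 TADs per chromosome, boundaries at intergenic gap midpoints
        n_bounds = 3 if len(gap_mids) >= 4 else max(len(gap_mids) - 1, 0)
        if n_bounds:
            picks = np.linspace(0, len(gap_mids) - 1, n_bounds + 2)[1:-1]
            bounds = sorted({gap_mids[int(round(p))] for p in picks})
        else:
            bounds = []
        edges = [0] + bounds + [length]
        tads[chrom] = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
        if ci == 0 and bounds:
            focal_boundary = bounds[len(bounds) // 2]

    if focal_boundary is None:
        raise ValueError(
            "infeasible geometry: too few genes on the first chromosome "
            "to place a TAD boundary"
        )

    focal = GeneModel(
        FOCAL_ID, chroms[0], "+",
        (((focal_boundary, focal_boundary + 600),
          (focal_boundary + 1200, focal_boundary + 2000)),),
    )
    genes.append(focal)
    info_rows[FOCAL_ID] = {
        "chrom": chroms[0], "tss": focal.tss, "strand": "+", "class": "focal",
    }

    gene_info = pd.DataFrame.from_dict(info_rows, orient="index").sort_index()
    focal_tads = TADMap(chroms[0], tuple(tads[chroms[0]]),
                        focal_boundary, FOCAL_ID)
    zones = assign_zones(gene_info, focal_tads)
    gene_info["zone"] = zones["zone"].reindex(gene_info.index)

    # true binding tiers (0 = unbound), independent of position
    tier = np.zeros(len(gene_info), dtype=int)
    non_focal = gene_info.index != FOCAL_ID
    bound = rng.random(len(gene_info)) < cfg.bound_fraction
    tier[bound & non_focal] = rng.integers(
        1, cfg.n_tiers + 1, size=int((bound & non_focal).sum())
    )
    gene_info["tier"] = tier

    return Annotation(genes, snos, tads, focal_tads, gene_info, chrom_lengths)


# ---------------------------------------------------------------------------
# counts

def _true_l2fc_genes(cfg: SimConfig, info: pd.DataFrame) -> pd.Series:
    """Planted per-gene log2FC from the configured effect channels."""
    l2fc = pd.Series(0.0, index=info.index)
    for name, off in cfg.effects.items():
        kind, _, value = name.partition(":")
        if kind == "class":
            l2fc[info["class"] == value] += off
        elif kind == "zone":
            l2fc[info["zone"] == value] += off
        elif kind == "tier":
            l2fc[info["tier"] == int(value)] += off
        elif kind == "gene":
            l2fc[info.index == value] += off
        elif kind == "region":
            pass  # region channels act on region-level counts only
        else:
            raise ValueError(f"unknown effect channel {name!r}")
    return l2fc


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean mu, variance mu + dispersion*mu^2) via gamma-Poisson."""
    if (mu < 0).any():
        raise ValueError("NB mean must be >= 0")
    if dispersion < 0:
        raise ValueError("NB dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=np.maximum(mu, 1e-300) * dispersion)
    return rng.poisson(lam)


def gen_counts(
    cfg: SimConfig, annotation: Annotation
) -> tuple[CountsTable, CountsTable, GroundTruth]:
    """Gene-level and region-level NB count tables plus the ground truth.

    Baseline per-gene means are log-normal and rescaled to the configured
    library size; planted effects multiply the mean by 2^offset in the
    knockdown condition only.  Region-level counts inherit the host's
    baseline, scaled by region length, with intronic regions at a fraction
    of the exonic rate and region-channel effects applied on top.
    """
    rng = cfg.rng("counts")
    info = annotation.gene_info
    n = len(info)

    base = rng.lognormal(mean=math.log(200.0), sigma=1.0, size=n)
    base *= cfg.library_size / base.sum()
    true_l2fc = _true_l2fc_genes(cfg, info)

    samples = [f"ctrl_{r + 1}" for r in range(cfg.n_replicates)] + \
              [f"kd_{r + 1}" for r in range(cfg.n_replicates)]
    conditions = pd.Series(
        ["ctrl"] * cfg.n_replicates + ["kd"] * cfg.n_replicates,
        index=samples,
    )
    cols = {}
    for s in samples:
        mu = base * np.where(conditions[s] == "kd",
                             2.0 ** true_l2fc.values, 1.0)
        cols[s] = _nb_draw(rng, mu, cfg.nb_dispersion)
    gene_counts = pd.DataFrame(cols, index=info.index)
    lengths = pd.Series(
        {g.gene_id: sum(e - s for s, e in g.exon_union()) for g in
         annotation.genes}
    ).reindex(info.index)
    gene_table = CountsTable(gene_counts, conditions, lengths)

    # region-level counts over the SNHG partitions
    parts, _ = annotation.partitions()
    region_rows = []
    base_by_gene = pd.Series(base, index=info.index)
    intron_rate = {"Exon": 1.0, "Snorna": 2.0, "Pre": 0.15, "Post": 0.1,
                   "OtherIntron": 0.05}
    for part in parts:
        host_rate = base_by_gene[part.host_id] / max(
            sum(s.length for s in part.segments if s.region.value == "Exon"),
            1,
        )
        host_l2fc = float(true_l2fc[part.host_id])
        for seg in part.segments:
            rid = part.region_id(seg)
            mu0 = host_rate * seg.length * intron_rate[seg.region.value]
            l2fc = host_l2fc + cfg.effects.get(
                f"region:{seg.region.value}", 0.0
            )
            region_rows.append((rid, part.host_id, seg.region.value,
                                seg.length, mu0, l2fc))
    region_truth = pd.DataFrame(
        region_rows,
        columns=["region", "host", "region_class", "length", "mu0",
                 "true_l2fc"],
    ).set_index("region")
    cols = {}
    for s in samples:
        mu = region_truth["mu0"].values * np.where(
            conditions[s] == "kd", 2.0 ** region_truth["true_l2fc"].values, 1.0
        )
        cols[s] = _nb_draw(rng, mu, cfg.nb_dispersion)
    region_counts = pd.DataFrame(cols, index=region_truth.index)
    region_table = CountsTable(
        region_counts, conditions,
        region_truth["length"].astype(float),
    )

    gene_truth = info.copy()
    gene_truth["true_l2fc"] = true_l2fc
    gene_truth["base_mean"] = base
    truth = GroundTruth(gene_truth=gene_truth, region_truth=region_truth)
    return gene_table, region_table, truth


# ---------------------------------------------------------------------------
# labeling time courses

def gen_label_timecourse(
    cfg: SimConfig,
    sigma: float,
    delta: float,
    times: Sequence[float] = (0.0, 4.0, 8.0, 24.0),
    depth: float = 200.0,
    feature_id: str = "feat",
    condition: str = "ctrl",
    rng: np.random.Generator | None = None,
    reference_abundance: float | None = None,
) -> LabelTimeCourse:
    """New/total counts under continuous labeling with known (sigma, delta).

    The expected new fraction at time t is 1 - exp(-delta t); new counts
    are binomial on Poisson totals.  The expected total is ``depth`` scaled
    by the feature's steady-state abundance sigma/delta relative to
    ``reference_abundance`` (default: its own, i.e. expected total =
    depth), so that changes in synthesis rate show up in the totals when
    two conditions share a reference.  ``depth=math.inf`` is a sentinel
    returning exact noiseless values with totals at the steady-state level.
    """
    if delta <= 0:
        raise ValueError("decay rate must be positive")
    times = np.asarray(sorted(times), dtype=float)
    if times[0] != 0.0:
        raise ValueError("times must include 0")
    frac = 1.0 - np.exp(-delta * times)
    steady = sigma / delta
    if math.isinf(depth):
        total = np.full(times.shape, steady)
        new = total * frac
        return LabelTimeCourse(feature_id, times, new, total, condition)
    if rng is None:
        rng = cfg.rng("timecourse")
    ref = reference_abundance if reference_abundance is not None else steady
    mean_total = depth * steady / ref
    total = rng.poisson(mean_total, size=times.shape).astype(float)
    new = rng.binomial(total.astype(int), frac).astype(float)
    return LabelTimeCourse(feature_id, times, new, total, condition)


def gen_timecourse_cohort(
    cfg: SimConfig,
    n_features: int = 200,
    halflife_range: tuple[float, float] = (1.0, 48.0),
    times: Sequence[float] = (0.0, 4.0, 8.0, 24.0),
    depth: float = 200.0,
) -> tuple[list[LabelTimeCourse], pd.DataFrame]:
    """A cohort of features with log-uniform half-lives and known rates."""
    rng = cfg.rng("timecourse")
    lo, hi = halflife_range
    halflives = np.exp(rng.uniform(math.log(lo), math.log(hi), n_features))
    deltas = math.log(2) / halflives
    sigmas = rng.lognormal(math.log(10.0), 0.5, n_features) * deltas
    courses = []
    rows = []
    for i, (s, d) in enumerate(zip(sigmas, deltas)):
        fid = f"F{i:04d}"
        courses.append(
            gen_label_timecourse(cfg, s, d, times, depth, fid, rng=rng)
        )
        rows.append({"feature": fid, "sigma": s, "delta": d,
                     "halflife": math.log(2) / d})
    return courses, pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# nuclear pixel intensities

def gen_nuclear_pixels(
    cfg: SimConfig,
    n_nuclei: int = 50,
    n_pixels: int = 400,
    mixture_weight: float = 0.0,
    baseline: tuple[float, float] = (4.0, 0.35),
    high: tuple[float, float] = (6.0, 0.25),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-nucleus pixel intensities from a two-component log-normal mix.

    ``mixture_weight`` is the fraction of pixels drawn from the bright
    component (a concentrated nucleolar-like signal); weight 0 gives a
    plain log-normal nucleoplasmic background.
    """
    if not 0.0 <= mixture_weight <= 1.0:
        raise ValueError("mixture weight must be in [0, 1]")
    if n_pixels < 100:
        raise ValueError("need >= 100 pixels per nucleus")
    rng = cfg.rng("pixels")
    rows = []
    for i in range(n_nuclei):
        from_high = rng.random(n_pixels) < mixture_weight
        vals = np.where(
            from_high,
            rng.lognormal(high[0], high[1], n_pixels),
            rng.lognormal(baseline[0], baseline[1], n_pixels),
        )
        for v in vals:
            rows.append((f"nuc{i:03d}", v))
    df = pd.DataFrame(rows, columns=["nucleus", "intensity"])
    truth = GroundTruth(
        gene_truth=pd.DataFrame(),
        pixel_truth=pd.DataFrame(
            {"nucleus": [f"nuc{i:03d}" for i in range(n_nuclei)],
             "mixture_weight": mixture_weight}
        ).set_index("nucleus"),
    )
    return df, truth


# ---------------------------------------------------------------------------
# screen inputs

def gen_screen_inputs(
    cfg: SimConfig,
    annotation: Annotation,
    n_lncs: int = 50,
    n_true_pairs: int = 5,
    conditions: Sequence[str] = ("condA", "condB"),
):
    """Regulatory elements and noiseless multi-condition DE tables with
    planted lncRNA-target pairs.

    The first ``n_lncs`` non-SNHG genes act as the lncRNA pool; each gets a
    regulatory element over its span targeting one other gene.  For the
    planted true pairs both the lncRNA and its target are called DE in the
    same direction in one condition; all other genes are ``ns``.  Returns
    (lnc_models, elements, de_tables, true_pairs).
    """
    from .screen import RegElement

    rng = cfg.rng("peaks")
    info = annotation.gene_info
    pool = [g for g in annotation.genes
            if info.loc[g.gene_id, "class"] == "regular"]
    if len(pool) < n_lncs + n_true_pairs:
        raise ValueError("not enough regular genes for the screen inputs")
    lncs = pool[:n_lncs]
    targets = pool[n_lncs:n_lncs + n_lncs]
    true_idx = sorted(
        rng.choice(min(n_lncs, len(targets)), size=n_true_pairs,
                   replace=False).tolist()
    )
    elements = []
    true_pairs = []
    for i, lnc in enumerate(lncs):
        if i >= len(targets):
            break
        tgt = targets[i].gene_id
        lo, hi = lnc.span
        elements.append(RegElement(f"GH{i:03d}", lnc.chrom, lo, hi, 1.0,
                                   (tgt,)))
        if i in true_idx:
            true_pairs.append((lnc.gene_id, tgt))

    all_ids = info.index.tolist()
    de_tables = {}
    for ci, cond in enumerate(conditions):
        calls = pd.Series("ns", index=all_ids)
        if ci == 0:
            for pi, (lnc_id, tgt_id) in enumerate(true_pairs):
                direction = "up" if pi % 2 == 0 else "down"
                calls[lnc_id] = direction
                calls[tgt_id] = direction
        de_tables[cond] = pd.DataFrame(
            {"baseMean": 100.0, "log2FC": 0.0, "pvalue": 1.0,
             "padj": 1.0, "call": calls}
        )
    return lncs, elements, de_tables, true_pairs


# ---------------------------------------------------------------------------
# reads and binding peaks

def gen_reads(
    cfg: SimConfig,
    partitions: Sequence[SNHGPartition],
    n_reads: int = 10_000,
    read_len: tuple[int, int] = (30, 100),
    sample: str = "s1",
) -> list[ReadInterval]:
    """Random reads over (and slightly past) the partitioned host spans."""
    rng = cfg.rng("reads")
    reads = []
    parts = list(partitions)
    for _ in range(n_reads):
        part = parts[int(rng.integers(len(parts)))]
        lo = part.segments[0].start
        hi = part.segments[-1].end
        length = int(rng.integers(read_len[0], read_len[1]))
        start = int(rng.integers(max(lo - length, 0), hi + length))
        reads.append(ReadInterval(part.chrom, start, start + length,
                                  sample=sample))
    return reads


def gen_peaks(cfg: SimConfig, annotation: Annotation) -> dict[str, list[Peak]]:
    """Binding peaks whose composite evidence grows with the true tier.

    Tier-k genes receive k peaks with signal and confidence increasing in
    k, so score-based tiering should broadly recover the planted ordering.
    """
    rng = cfg.rng("peaks")
    out: dict[str, list[Peak]] = {}
    for gene_id, row in annotation.gene_info.iterrows():
        t = int(row["tier"])
        if t == 0:
            out[gene_id] = []
            continue
        peaks = []
        for _ in range(t):
            signal = float(rng.gamma(2.0, 1.0) * t)
            neglogp = float(rng.uniform(1.0, 2.0) * t)
            peaks.append(Peak(signal, 10.0 ** -neglogp))
        out[gene_id] = peaks
    return out
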