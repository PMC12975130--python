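"""Read-to-region assignment and count normalization.

Region-level counting uses a majority-overlap rule: each read is credited
to the single region class covering most of its aligned bases, with ties
broken in favor of the shorter, biologically focal classes
(Snorna > Pre > Post > Exon > OtherIntron).  Normalization follows the
median-of-ratios scheme standard in bulk RNA-seq.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .partition import CLASS_PRIORITY, SNHGPartition


@dataclass(frozen=True)
class ReadInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    sample: str = "s1"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read interval must have positive length")


@dataclass
class CountsTable:
    """Feature x sample integer counts with a condition label per sample.

    ``counts`` is a DataFrame indexed by feature id with sample columns;
    ``conditions`` maps sample -> condition label; ``lengths`` (optional)
    maps feature -> feature length in nt.
    """

    counts: pd.DataFrame
    conditions: pd.Series
    lengths: pd.Series | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if self.lengths is not None and (self.lengths <= 0).any():
            raise ValueError("feature lengths must be positive")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


def assign_reads(
    reads: Sequence[ReadInterval],
    partitions: Sequence[SNHGPartition],
    samples: Sequence[str] | None = None,
) -> CountsTable:
    """Count reads per partition region (majority-overlap, one region/read).

    Reads that overlap no host span, or sit on a chromosome absent from the
    partition set, are ignored and tallied in ``diagnostics``.
    """
    trees: dict[str, IntervalTree] = {}
    region_ids: list[str] = []
    for part in partitions:
        tree = trees.setdefault(part.chrom, IntervalTree())
        for seg in part.segments:
            rid = part.region_id(seg)
            region_ids.append(rid)
            tree[seg.start:seg.end] = (rid, CLASS_PRIORITY[seg.region])

    if samples is None:
        samples = sorted({r.sample for r in reads}) or ["s1"]
    counts = {s: dict.fromkeys(region_ids, 0) for s in samples}
    ignored = {"no_chrom": 0, "no_host": 0}

    for read in reads:
        tree = trees.get(read.chrom)
        if tree is None:
            ignored["no_chrom"] += 1
            continue
        hits = tree.overlap(read.start, read.end)
        if not hits:
            ignored["no_host"] += 1
            continue
        # majority overlap; ties by class priority, then region id
        best = max(
            hits,
            key=lambda iv: (
                min(iv.end, read.end) - max(iv.begin, read.start),
                iv.data[1],
                iv.data[0],
            ),
        )
        counts[read.sample][best.data[0]] += 1

    df = pd.DataFrame(counts, columns=list(samples)).fillna(0).astype(int)
    df = df.reindex(region_ids)
    conditions = pd.Series({s: s for s in samples})
    return CountsTable(df, conditions, diagnostics={"ignored_reads": ignored})


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    For features with nonzero counts in every sample, the factor of sample
    *j* is the median of count_ij / geometric-mean_i.
    """
    mat = counts.values.astype(float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has nonzero counts in all samples")
    sub = mat[positive]
    log_geo = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts divided by their median-of-ratios size factors."""
    return counts / size_factors(counts)


def fpkm(
    counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series | None = None
) -> pd.DataFrame:
    """Fragments per kilobase of feature per million assigned reads.

    fpkm_ij = count_ij * 1e9 / (length_i * total_j); ``totals`` defaults to
    the per-sample column sums.
    """
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.astype(float)
    if (totals <= 0).any():
        raise ValueError("per-sample totals must be positive")
    lengths = lengths.reindex(counts.index).astype(float)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all features need a positive length")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
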