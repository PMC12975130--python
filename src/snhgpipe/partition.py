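"""Custom region annotation for snoRNA host genes (SNHGs).

Intronic snoRNAs are processed out of their host transcript's introns, so
the fate of a host gene's RNA differs by region: spliced exons, the intronic
sequence transcribed before the snoRNA (``Pre``), the snoRNA itself, the
intronic sequence after it (``Post``), and introns with no snoRNA
(``OtherIntron``).  Quantifying these regions separately resolves where
along the host gene a perturbation acts.

All coordinates are 0-based half-open; conversion to/from GTF's 1-based
closed convention happens only in :mod:`snhgpipe.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class RegionClass(str, Enum):
    EXON = "Exon"
    PRE = "Pre"
    SNORNA = "Snorna"
    POST = "Post"
    OTHER_INTRON = "OtherIntron"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Tie-break priority for read assignment (highest wins).
CLASS_PRIORITY = {
    RegionClass.SNORNA: 5,
    RegionClass.PRE: 4,
    RegionClass.POST: 3,
    RegionClass.EXON: 2,
    RegionClass.OTHER_INTRON: 1,
}


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more isoforms, each a sorted list of exons."""

    gene_id: str
    chrom: str
    strand: str
    isoforms: tuple[tuple[tuple[int, int], ...], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.isoforms:
            raise ValueError(f"gene {self.gene_id} has no isoforms")
        for iso in self.isoforms:
            if not iso:
                raise ValueError(f"gene {self.gene_id} has an empty isoform")
            for (s, e) in iso:
                if e <= s:
                    raise ValueError(
                        f"gene {self.gene_id}: empty exon [{s},{e})"
                    )
            for (_, e0), (s1, _) in zip(iso, iso[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"gene {self.gene_id}: exons overlap or unsorted"
                    )

    @property
    def span(self) -> tuple[int, int]:
        """Merged genomic span over all isoforms."""
        starts = [iso[0][0] for iso in self.isoforms]
        ends = [iso[-1][1] for iso in self.isoforms]
        return min(starts), max(ends)

    @property
    def tss(self) -> int:
        lo, hi = self.span
        return lo if self.strand == "+" else hi - 1

    def exon_union(self) -> list[tuple[int, int]]:
        return merge_intervals(
            iv for iso in self.isoforms for iv in iso
        )


@dataclass(frozen=True)
class SnoRecord:
    """An intronic snoRNA and the host gene it is embedded in."""

    sno_id: str
    host_id: str
    start: int
    end: int
    sno_class: str = "other"  # C/D, H/ACA, scaRNA, other

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"snoRNA {self.sno_id}: empty interval")


@dataclass(frozen=True)
class Segment:
    start: int
    end: int
    region: RegionClass
    sno_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty segment")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SNHGPartition:
    """Disjoint labeled segments covering the merged span of one host."""

    host_id: str
    chrom: str
    strand: str
    segments: list[Segment] = field(default_factory=list)

    def region_id(self, seg: Segment) -> str:
        """Stable feature id for a segment, e.g. ``HOST:Pre:sno1``."""
        if seg.sno_id is not None:
            return f"{self.host_id}:{seg.region.value}:{seg.sno_id}"
        return f"{self.host_id}:{seg.region.value}:{seg.start}"


class PartitionError(ValueError):
    """The host/snoRNA geometry violates the partition scheme."""


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    ivs = sorted(ivs)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _complement(span: tuple[int, int], ivs: Sequence[tuple[int, int]]):
    """Gaps of `span` not covered by the sorted disjoint `ivs`."""
    lo, hi = span
    gaps = []
    cur = lo
    for s, e in ivs:
        if s > cur:
            gaps.append((cur, s))
        cur = max(cur, e)
    if cur < hi:
        gaps.append((cur, hi))
    return gaps


def partition_snhg(
    model: GeneModel, snos: Sequence[SnoRecord]
) -> SNHGPartition:
    """Partition one host gene into Exon/Pre/Snorna/Post/OtherIntron segments.

    Exons are the union over all isoforms; introns are the merged span minus
    that union.  Each snoRNA-containing intron is cut at the snoRNA
    boundaries: the transcriptionally upstream piece becomes ``Pre`` and the
    downstream piece ``Post`` (mirrored on the minus strand).  When one
    intron hosts several snoRNAs, the gap between two snoRNAs is split at
    its midpoint so Pre/Post stay uniquely attributed.

    Raises
    ------
    PartitionError
        If a snoRNA overlaps the exon union (the scheme presumes fully
        intronic snoRNAs; callers exclude such hosts).
    ValueError
        If a snoRNA lies outside the merged host span or is not hosted by
        ``model``.
    """
    for sno in snos:
        if sno.host_id != model.gene_id:
            raise ValueError(
                f"snoRNA {sno.sno_id} hosted by {sno.host_id}, "
                f"not {model.gene_id}"
            )
    span = model.span
    exons = model.exon_union()
    for sno in snos:
        if sno.start < span[0] or sno.end > span[1]:
            raise ValueError(
                f"snoRNA {sno.sno_id} outside merged span of {model.gene_id}"
            )
        for s, e in exons:
            if sno.start < e and s < sno.end:
                raise PartitionError(
                    f"snoRNA {sno.sno_id} overlaps exon union of "
                    f"{model.gene_id}"
                )

    part = SNHGPartition(model.gene_id, model.chrom, model.strand)
    segs: list[Segment] = [
        Segment(s, e, RegionClass.EXON) for s, e in exons
    ]
    plus = model.strand == "+"
    for intron in _complement(span, exons):
        inside = sorted(
            (s for s in snos if intron[0] <= s.start and s.end <= intron[1]),
            key=lambda s: s.start,
        )
        if not inside:
            segs.append(Segment(*intron, RegionClass.OTHER_INTRON))
            continue
        # boundaries between consecutive snoRNAs: midpoint of the gap,
        # rounding toward the transcriptionally downstream side so that
        # coordinate reflection + strand flip is an exact symmetry
        cuts = [intron[0]]
        for a, b in zip(inside, inside[1:]):
            cuts.append((a.end + b.start + (0 if plus else 1)) // 2)
        cuts.append(intron[1])
        for i, sno in enumerate(inside):
            left = (cuts[i], sno.start)
            right = (sno.end, cuts[i + 1])
            segs.append(Segment(sno.start, sno.end, RegionClass.SNORNA, sno.sno_id))
            if left[1] > left[0]:
                cls = RegionClass.PRE if plus else RegionClass.POST
                segs.append(Segment(*left, cls, sno.sno_id))
            if right[1] > right[0]:
                cls = RegionClass.POST if plus else RegionClass.PRE
                segs.append(Segment(*right, cls, sno.sno_id))
    part.segments = sorted(segs, key=lambda s: s.start)
    return part


def partition_all(
    models: Sequence[GeneModel], snos: Sequence[SnoRecord]
) -> tuple[list[SNHGPartition], list[str]]:
    """Partition every host with at least one snoRNA.

    Returns partitions ordered by gene id plus a list of diagnostics for
    hosts that were excluded (snoRNA overlapping the exon union).
    """
    ids = [m.gene_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in models")
    by_host: dict[str, list[SnoRecord]] = {}
    for sno in snos:
        by_host.setdefault(sno.host_id, []).append(sno)
    known = set(ids)
    for host in by_host:
        if host not in known:
            raise ValueError(f"snoRNA host {host} not among gene models")

    out: list[SNHGPartition] = []
    diagnostics: list[str] = []
    for model in sorted(models, key=lambda m: m.gene_id):
        hosted = by_host.get(model.gene_id)
        if not hosted:
            continue
        try:
            out.append(partition_snhg(model, hosted))
        except PartitionError as exc:
            diagnostics.append(str(exc))
    return out, diagnostics
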