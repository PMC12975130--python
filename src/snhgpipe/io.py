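"""Standard-format I/O: GTF, BED, narrowPeak, TSV and JSON reports.

All in-memory coordinates are 0-based half-open.  GTF is 1-based closed
and BED 0-based half-open per their standards; the conversion happens here
and nowhere else.  TSVs are tab-delimited with a header row, UTF-8, '.'
for missing values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pyranges as pr

from .partition import GeneModel, SnoRecord, SNHGPartition
from .quantify import CountsTable
from .tiers import Peak


# ---------------------------------------------------------------------------
# GTF

def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GTF exon records (1-based closed coordinates)."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
            for ti, iso in enumerate(g.isoforms):
                tid = f"{g.gene_id}.t{ti + 1}"
                for s, e in iso:
                    attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                    fh.write(
                        f"{g.chrom}\tsnhgpipe\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )


def load_gene_models(path) -> list[GeneModel]:
    """Read gene models from GTF; exons grouped by transcript then gene."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pr.read_gtf(str(path)).df
    df = df[df["Feature"] == "exon"]
    if df.empty:
        return []
    models = []
    for gene_id, gdf in df.groupby("gene_id", sort=True):
        chroms = gdf["Chromosome"].unique()
        strands = gdf["Strand"].unique()
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"gene {gene_id}: exons span multiple chromosomes/strands"
            )
        isoforms = []
        for _, tdf in gdf.groupby("transcript_id", sort=True):
            exons = sorted(
                (int(s), int(e))
                for s, e in zip(tdf["Start"], tdf["End"])
            )
            isoforms.append(tuple(exons))
        models.append(
            GeneModel(str(gene_id), str(chroms[0]), str(strands[0]),
                      tuple(isoforms))
        )
    return models


# ---------------------------------------------------------------------------
# BED

def write_bed6(records, path) -> None:
    """Write (chrom, start, end, name, score, strand) tuples as BED6."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_annotation(genes, snos, tads, path_prefix) -> dict:
    """Write GTF + snoRNA BED/host map + TAD BED3; returns the paths."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": prefix.with_suffix(".gtf"),
        "sno_bed": Path(f"{prefix}.snos.bed"),
        "sno_hosts": Path(f"{prefix}.sno_hosts.tsv"),
        "tad_bed": Path(f"{prefix}.tads.bed"),
    }
    write_gtf(genes, paths["gtf"])
    chrom_of = {g.gene_id: g.chrom for g in genes}
    write_bed6(
        [(chrom_of[s.host_id], s.start, s.end, s.sno_id, 0, "+")
         for s in snos],
        paths["sno_bed"],
    )
    pd.DataFrame(
        {"sno_id": [s.sno_id for s in snos],
         "host_id": [s.host_id for s in snos],
         "sno_class": [s.sno_class for s in snos]}
    ).to_csv(paths["sno_hosts"], sep="\t", index=False)
    with open(paths["tad_bed"], "w", encoding="utf-8") as fh:
        for chrom in sorted(tads):
            for s, e in tads[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    return {k: str(v) for k, v in paths.items()}


def load_snos(bed_path, host_map_path) -> list[SnoRecord]:
    """Read snoRNAs from BED6 plus the snoRNA-to-host mapping TSV."""
    bed = pr.read_bed(str(bed_path)).df
    hosts = pd.read_csv(host_map_path, sep="\t").set_index("sno_id")
    out = []
    for _, row in bed.iterrows():
        sno_id = str(row["Name"])
        if sno_id not in hosts.index:
            raise ValueError(f"snoRNA {sno_id} missing from host map")
        out.append(
            SnoRecord(sno_id, str(hosts.loc[sno_id, "host_id"]),
                      int(row["Start"]), int(row["End"]),
                      str(hosts.loc[sno_id, "sno_class"]))
        )
    return out


def write_partitions(parts: Sequence[SNHGPartition], bed_path,
                     index_path) -> None:
    """Partitions as BED6 (region class in the name) plus a TSV index."""
    rows = []
    with open(bed_path, "w", encoding="utf-8") as fh:
        for part in parts:
            for seg in part.segments:
                rid = part.region_id(seg)
                name = f"{rid}|{seg.region.value}"
                fh.write(
                    f"{part.chrom}\t{seg.start}\t{seg.end}\t{name}\t0\t"
                    f"{part.strand}\n"
                )
                rows.append(
                    (rid, part.host_id, seg.region.value, part.chrom,
                     seg.start, seg.end, part.strand,
                     seg.sno_id if seg.sno_id else ".")
                )
    pd.DataFrame(
        rows,
        columns=["region", "host", "region_class", "chrom", "start", "end",
                 "strand", "sno_id"],
    ).to_csv(index_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts / generic tables

def write_counts(table: CountsTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")
    meta = Path(str(path) + ".conditions")
    table.conditions.rename("condition").to_frame().rename_axis(
        "sample"
    ).to_csv(meta, sep="\t")


def load_counts(path) -> CountsTable:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = None
    cond = pd.read_csv(str(path) + ".conditions", sep="\t",
                       index_col=0)["condition"]
    cond.index.name = None
    return CountsTable(counts.astype(int), cond)


def read_narrowpeak(path) -> dict[str, list[Peak]]:
    """narrowPeak -> per-gene Peak lists; the name column carries the gene.

    Uses the standard columns: signalValue (7th) and pValue (8th,
    -log10-scaled per the ENCODE convention).
    """
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signalValue", "pValue", "qValue", "peak"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    out: dict[str, list[Peak]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["name"]), []).append(
            Peak(float(row["signalValue"]), 10.0 ** -float(row["pValue"]))
        )
    return out


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return dict(obj)
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
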