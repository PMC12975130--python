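"""Positional cis/trans analysis against TAD structure.

Genes are classed by the position of their TSS relative to a focal locus
sitting at a TAD boundary: inside either of the two TADs sharing that
boundary (``Cis``), elsewhere on the same chromosome (``SameChromosome``),
or on another chromosome (``Trans``).  Cis action is then tested as an
enrichment of significant same-direction genes in the Cis zone, and 4C-style
contact counts over a genomic interval are compared between conditions with
a chi-squared test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import group_shift

ZONES = ("Cis", "SameChromosome", "Trans")


@dataclass(frozen=True)
class TADMap:
    """Sorted, non-overlapping TADs on one chromosome plus a focal boundary.

    The focal boundary must coincide with the shared edge of two adjacent
    TADs; the focal locus (the lncRNA under study) sits at that boundary.
    """

    chrom: str
    tads: tuple[tuple[int, int], ...]
    focal_boundary: int
    focal_id: str

    def __post_init__(self) -> None:
        for (s, e) in self.tads:
            if e <= s:
                raise ValueError("empty TAD interval")
        for (_, e0), (s1, _) in zip(self.tads, self.tads[1:]):
            if s1 < e0:
                raise ValueError("TADs must be sorted and non-overlapping")
        edges = {e for _, e in self.tads[:-1]} & {s for s, _ in self.tads[1:]}
        if self.focal_boundary not in edges:
            raise ValueError(
                "focal boundary must be the shared edge of two adjacent TADs"
            )

    @property
    def flanking_tads(self) -> tuple[tuple[int, int], tuple[int, int]]:
        left = next(t for t in self.tads if t[1] == self.focal_boundary)
        right = next(t for t in self.tads if t[0] == self.focal_boundary)
        return left, right


def assign_zones(genes: pd.DataFrame, tads: TADMap) -> pd.DataFrame:
    """Zone per gene from a frame with ``chrom`` and ``tss`` columns.

    The focal locus itself is excluded; genes with a missing TSS are
    skipped and reported in the ``skipped`` attribute of the result frame.
    """
    left, right = tads.flanking_tads
    records = {}
    skipped = []
    for gene_id, row in genes.iterrows():
        if gene_id == tads.focal_id:
            continue
        if pd.isna(row["tss"]):
            skipped.append(gene_id)
            continue
        tss = int(row["tss"])
        if row["chrom"] != tads.chrom:
            zone = "Trans"
        elif left[0] <= tss < left[1] or right[0] <= tss < right[1]:
            zone = "Cis"
        else:
            zone = "SameChromosome"
        records[gene_id] = zone
    out = pd.DataFrame({"zone": pd.Series(records, dtype=object)})
    out.attrs["skipped"] = skipped
    return out


def zone_effect_test(
    de_results: pd.DataFrame, zones: pd.DataFrame, min_genes: int = 5
) -> dict:
    """Group-shift tests of log2FC across zones.

    Zones with fewer than ``min_genes`` tested genes are flagged and left
    out of the tests.
    """
    merged = de_results.join(zones, how="inner")
    merged = merged[merged["call"] != "filtered"].dropna(subset=["log2FC"])
    sizes = merged["zone"].value_counts()
    small = [z for z in ZONES if sizes.get(z, 0) < min_genes]
    usable = merged[~merged["zone"].isin(small)]
    if usable["zone"].nunique() < 2:
        raise ValueError("fewer than 2 zones with enough genes to test")
    result = group_shift(usable["log2FC"].values, usable["zone"].values)
    result["excluded_zones"] = small
    return result


def digital_cis_test(
    de_results: pd.DataFrame, zones: pd.DataFrame, direction: str
) -> dict:
    """Fisher-exact enrichment of significant same-direction genes in Cis.

    Builds the 2x2 table {significant in ``direction``, not} x
    {Cis, elsewhere}; returns the two-sided Fisher p and an odds ratio with
    a Haldane (+0.5) correction when any cell is zero.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    merged = de_results.join(zones, how="inner")
    merged = merged[merged["call"] != "filtered"]
    if not (merged["zone"] == "Cis").any():
        raise ValueError("no genes in the Cis zone")
    sig = merged["call"] == direction
    cis = merged["zone"] == "Cis"
    if not sig.any():
        raise ValueError(f"no significant '{direction}' genes")
    table = np.array(
        [
            [int((sig & cis).sum()), int((sig & ~cis).sum())],
            [int((~sig & cis).sum()), int((~sig & ~cis).sum())],
        ]
    )
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if (table == 0).any():
        t = table + 0.5
        odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    else:
        odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return {"table": table.tolist(), "odds_ratio": odds, "p": p}


def contact_interval_test(
    in_interval: Sequence[int], totals: Sequence[int]
) -> dict:
    """Chi-squared comparison of contact counts inside a genomic interval.

    ``in_interval`` and ``totals`` give, for each of two conditions, the
    UMI count falling in the quantified interval and the total count.
    Pearson chi-squared without continuity correction, df = 1.  Expected
    cells below 1 (including degenerate margins) attach a warning rather
    than failing.
    """
    (a_in, b_in), (a_tot, b_tot) = in_interval, totals
    if min(a_in, b_in) < 0 or a_tot < a_in or b_tot < b_in:
        raise ValueError("need 0 <= in-interval counts <= totals")
    obs = np.array([[a_in, a_tot - a_in], [b_in, b_tot - b_in]], dtype=float)
    out: dict = {"table": obs.astype(int).tolist()}
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        out.update(chi2=0.0, p=1.0, warning="degenerate margin")
        return out
    expected = row @ col / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    out["chi2"] = chi2
    out["p"] = float(stats.chi2.sf(chi2, df=1))
    if (expected < 1).any():
        out["warning"] = "expected cell below 1"
    return out
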