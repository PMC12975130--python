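"""Candidate cis-acting lncRNA screen.

Integrates a regulatory-element/target map (GeneHancer-style: elements with
confidence scores and assigned target genes) with differential-expression
tables from several perturbation conditions.  A lncRNA-target pair is a
candidate when (1) the lncRNA locus overlaps a sufficiently confident
element, (2) the lncRNA is differentially expressed in at least one
condition, and (3) a target of that element is differentially expressed in
the same condition.  Concordance (both moving in the same direction) is
tracked per pair and required for the final set by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .partition import GeneModel


@dataclass(frozen=True)
class RegElement:
    element_id: str
    chrom: str
    start: int
    end: int
    score: float
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"element {self.element_id} has no targets")


@dataclass
class ScreenCandidate:
    lnc_id: str
    element_id: str
    target_id: str
    conditions: list[str] = field(default_factory=list)
    concordant: bool = False


def _is_de(de: pd.DataFrame, gene: str) -> str | None:
    if gene not in de.index:
        return None
    call = de.loc[gene, "call"]
    return call if call in ("up", "down") else None


def run_screen(
    lnc_models: Sequence[GeneModel],
    elements: Sequence[RegElement],
    de_tables: Mapping[str, pd.DataFrame],
    min_confidence: float = 1.0,
    require_concordance: bool = True,
) -> list[ScreenCandidate]:
    """Emit candidate (lncRNA, target) pairs supported by >=1 condition.

    ``de_tables`` maps condition name to a DE result frame (index feature
    id, columns including ``call``).  The lncRNA-element overlap is any
    genomic overlap of the lncRNA gene span.  With
    ``require_concordance=False`` pairs qualify whenever both genes are DE
    in the same condition regardless of direction; the concordance flag is
    reported either way (true when some supporting condition moves both
    genes the same way).
    """
    if not elements:
        warnings.warn("empty regulatory-element table; screen returns nothing")
        return []
    candidates: dict[tuple[str, str, str], ScreenCandidate] = {}
    for lnc in sorted(lnc_models, key=lambda m: m.gene_id):
        lo, hi = lnc.span
        for el in elements:
            if el.score < min_confidence or el.chrom != lnc.chrom:
                continue
            if not (el.start < hi and lo < el.end):
                continue
            for target in el.targets:
                if target == lnc.gene_id:
                    continue
                support: list[str] = []
                concordant = False
                for cond in sorted(de_tables):
                    lnc_call = _is_de(de_tables[cond], lnc.gene_id)
                    tgt_call = _is_de(de_tables[cond], target)
                    if lnc_call is None or tgt_call is None:
                        continue
                    same_dir = lnc_call == tgt_call
                    if require_concordance and not same_dir:
                        continue
                    support.append(cond)
                    concordant = concordant or same_dir
                if support:
                    key = (lnc.gene_id, el.element_id, target)
                    candidates[key] = ScreenCandidate(
                        lnc.gene_id, el.element_id, target,
                        conditions=support, concordant=concordant,
                    )
    return [candidates[k] for k in sorted(candidates)]


def rank_candidates(
    candidates: Sequence[ScreenCandidate],
    de_tables: Mapping[str, pd.DataFrame],
) -> list[ScreenCandidate]:
    """Order candidates for follow-up.

    Sort key: number of supporting conditions, then lncRNA expression
    (mean baseMean over its supporting conditions), both descending, with a
    stable lexicographic tie-break on (lncRNA, element, target) ids.
    """
    if not candidates:
        raise ValueError("no candidates to rank")

    def expression(c: ScreenCandidate) -> float:
        means = [
            float(de_tables[cond].loc[c.lnc_id, "baseMean"])
            for cond in c.conditions
            if c.lnc_id in de_tables[cond].index
        ]
        return sum(means) / len(means) if means else 0.0

    return sorted(
        candidates,
        key=lambda c: (
            -len(c.conditions),
            -expression(c),
            c.lnc_id,
            c.element_id,
            c.target_id,
        ),
    )
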