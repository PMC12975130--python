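"""Binding-confidence tiering and the tiered-downregulation trend test.

Genes with protein-RNA binding evidence (eCLIP peaks or RIP enrichment)
are scored by the number, strength and confidence of their binding sites,
split into quantile tiers (tier 0 = unbound), compared against
expression-matched unbound controls, and tested for a monotone
fold-change trend across tiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import de_test, group_shift
from .quantify import CountsTable

#: Cap on a single peak's -log10(p) contribution to the composite score.
NEG_LOG10P_CAP = 10.0


@dataclass(frozen=True)
class Peak:
    signal: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("peak signal must be >= 0")
        if not 0 < self.pvalue <= 1:
            raise ValueError("peak p value must be in (0, 1]")


def score_binding(evidence: Mapping[str, Sequence[Peak]]) -> pd.Series:
    """Composite binding score: sum over peaks of signal * min(-log10 p, cap).

    Genes without peaks score 0.
    """
    scores = {
        gene: float(
            sum(
                pk.signal * min(-np.log10(pk.pvalue), NEG_LOG10P_CAP)
                for pk in peaks
            )
        )
        for gene, peaks in evidence.items()
    }
    return pd.Series(scores, name="binding_score", dtype=float)


def assign_tiers(scores: pd.Series, k: int = 4) -> pd.Series:
    """Quantile tiers 1..k over bound genes (score > 0); unbound get tier 0.

    The split is rank-based so tier sizes differ by at most one for
    distinct scores; tied scores all land in the lowest tier the tie group
    touches.  If there are fewer bound genes than tiers, k is reduced with
    a warning.
    """
    if k < 2:
        raise ValueError("need at least 2 tiers")
    tiers = pd.Series(0, index=scores.index, dtype=int, name="tier")
    bound = scores[scores > 0].sort_values(kind="mergesort")
    n = len(bound)
    if n == 0:
        return tiers
    if n < k:
        warnings.warn(f"only {n} bound genes; reducing tiers from {k} to {n}")
        k = max(n, 1)
    raw = np.minimum((np.arange(n) * k) // n + 1, k)
    # ties take the lowest tier in their group
    tier_of_score: dict[float, int] = {}
    for s, t in zip(bound.values, raw):
        tier_of_score.setdefault(s, int(t))
    tiers[bound.index] = [tier_of_score[s] for s in bound.values]
    if len(set(tier_of_score.values())) < k <= n:
        warnings.warn("tied scores collapsed one or more tiers")
    return tiers


def matched_controls(
    tiers: pd.Series,
    expression: pd.Series,
    n_bins: int = 10,
    seed: int = 0,
) -> dict[int, list[str]]:
    """Expression-matched unbound control sets, one per populated tier.

    Expression bins (deciles by default) are computed over all genes; for
    each tier >= 1 the unbound (tier 0) genes are sampled without
    replacement to reproduce the tier's bin histogram.  Bins with targets
    but no unbound genes are dropped with a warning; bins with too few
    controls contribute all they have.
    """
    expression = expression.reindex(tiers.index)
    if expression.isna().any():
        raise ValueError("expression values required for all genes")
    edges = np.quantile(expression.values, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    bins = pd.Series(
        np.clip(np.searchsorted(edges, expression.values, side="right") - 1,
                0, len(edges) - 2),
        index=tiers.index,
    )
    rng = np.random.default_rng(seed)
    pool: dict[int, list[str]] = {}
    for gene, b in bins[tiers == 0].items():
        pool.setdefault(int(b), []).append(gene)
    out: dict[int, list[str]] = {}
    for tier in sorted(t for t in tiers.unique() if t > 0):
        members = bins[tiers == tier]
        chosen: list[str] = []
        for b, count in members.value_counts().items():
            avail = pool.get(b, [])
            if not avail:
                warnings.warn(
                    f"tier {tier}: expression bin {b} has no unbound genes"
                )
                continue
            take = min(count, len(avail))
            if take < count:
                warnings.warn(
                    f"tier {tier}: bin {b} has only {take}/{count} controls"
                )
            chosen.extend(
                sorted(rng.choice(avail, size=take, replace=False).tolist())
            )
        out[int(tier)] = sorted(chosen)
    return out


def tier_trend_test(tiers: pd.Series, de_results: pd.DataFrame) -> dict:
    """Per-tier Mann-Whitney vs tier 0 plus Spearman(tier, log2FC).

    A negative Spearman rho with small p indicates stronger downregulation
    in higher-confidence tiers.
    """
    merged = pd.DataFrame({"tier": tiers}).join(de_results, how="inner")
    merged = merged[merged["call"] != "filtered"].dropna(subset=["log2FC"])
    populated = sorted(merged["tier"].unique())
    if len(populated) < 2:
        raise ValueError("need at least 2 populated tiers")
    shift = group_shift(merged["log2FC"].values, merged["tier"].values)
    rho, rho_p = stats.spearmanr(merged["tier"].values, merged["log2FC"].values)
    vs_tier0 = {
        t: shift["pairwise"][(0, t)]
        for t in populated
        if t != 0 and (0, t) in shift["pairwise"]
    }
    return {
        "group_shift": shift,
        "vs_tier0": vs_tier0,
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
    }


def rip_enrichment(
    table: CountsTable,
    input_label: str,
    ip_label: str,
    thresholds=None,
) -> tuple[set[str], pd.DataFrame]:
    """Genes enriched in the IP fraction over input.

    Runs the standard DE test with IP as the treated condition; enriched
    genes are those called ``up`` (padj and fold-change gates both apply).
    """
    de = de_test(table, control=input_label, treated=ip_label,
                 thresholds=thresholds)
    return set(de.index[de["call"] == "up"]), de
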