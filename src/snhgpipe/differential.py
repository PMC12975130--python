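"""Differential expression and the group-shift statistics.

The decision rule is the study-style threshold pair: BH-adjusted p < 0.05
and |log2 fold change| > 0.41 (a ~33% change), after filtering features
that are poorly expressed or shorter than 200 nt of exonic sequence.  The
test itself is deliberately simple and calibration-checked: median-of-ratios
normalization, pseudocounted log2 fold change of group means, and a Welch
t-test on log2(normalized count + pseudocount).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountsTable, size_factors


@dataclass(frozen=True)
class DEThresholds:
    padj_cutoff: float = 0.05
    lfc_cutoff: float = 0.41
    min_mean_count: float = 5.0
    min_length: int = 200
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if min(self.padj_cutoff, self.lfc_cutoff, self.pseudocount) <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def min_detectable_change_pct(self) -> float:
        """The fold-change cutoff expressed as a percent change."""
        return (2.0 ** self.lfc_cutoff - 1.0) * 100.0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (NaN passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        pm = p[mask]
        if (pm < 0).any() or (pm > 1).any():
            raise ValueError("p values must lie in [0, 1]")
        out[mask] = multipletests(pm, method="fdr_bh")[1]
    return out


def _welch_log(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p per row; degenerate rows by convention.

    Zero variance in both groups gives p = 1 when means agree (nothing to
    call) and p = 0 when they differ (perfect separation).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    var0 = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    same = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[var0 & same] = 1.0
    p[var0 & ~same] = 0.0
    return p


def de_test(
    table: CountsTable,
    control: str,
    treated: str,
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """Per-feature DE table: baseMean, log2FC, p, padj and a call.

    Calls are ``up`` / ``down`` / ``ns`` under the thresholds, or
    ``filtered`` for features excluded before testing (all-zero, mean
    normalized count below the floor, or exonic length under the minimum
    when lengths are available).  BH correction runs over the tested
    features only.
    """
    th = thresholds or DEThresholds()
    ctrl_cols = table.samples_for(control)
    trt_cols = table.samples_for(treated)
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("each condition needs at least 2 replicates")

    counts = table.counts[ctrl_cols + trt_cols]
    norm = counts / size_factors(counts)
    a = norm[trt_cols].values
    b = norm[ctrl_cols].values
    c = th.pseudocount

    base_mean = norm.values.mean(axis=1)
    lfc = np.log2((a.mean(axis=1) + c) / (b.mean(axis=1) + c))

    keep = (counts.values.sum(axis=1) > 0) & (base_mean >= th.min_mean_count)
    if table.lengths is not None:
        lens = table.lengths.reindex(counts.index).values
        keep &= ~(lens < th.min_length)

    p = np.full(len(counts), np.nan)
    p[keep] = _welch_log(np.log2(a + c)[keep], np.log2(b + c)[keep])
    padj = bh_adjust(p)

    call = np.where(
        ~keep,
        "filtered",
        np.where(
            (padj < th.padj_cutoff) & (np.abs(lfc) > th.lfc_cutoff),
            np.where(lfc > 0, "up", "down"),
            "ns",
        ),
    )
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": lfc,
            "pvalue": p,
            "padj": padj,
            "call": call,
        },
        index=counts.index,
    )


def group_shift(values, labels) -> dict:
    """Pairwise Mann-Whitney tests plus a global one-way ANOVA.

    ``values`` are per-feature statistics (typically log2 fold changes) and
    ``labels`` their class labels.  The Mann-Whitney test is exact when the
    smaller group has at most 8 members, otherwise a tie-corrected normal
    approximation is used.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("group_shift needs at least 2 classes")
    groups = {c: values[labels == c] for c in classes}
    for c, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 values")

    pairwise = {}
    for i, ca in enumerate(classes):
        for cb in classes[i + 1:]:
            ga, gb = groups[ca], groups[cb]
            method = "exact" if min(len(ga), len(gb)) <= 8 else "asymptotic"
            try:
                res = stats.mannwhitneyu(
                    ga, gb, alternative="two-sided", method=method
                )
            except ValueError:  # exact method refuses ties
                res = stats.mannwhitneyu(
                    ga, gb, alternative="two-sided", method="asymptotic"
                )
            pairwise[(ca, cb)] = {"U": float(res.statistic), "p": float(res.pvalue)}

    anova_p = float(stats.f_oneway(*groups.values()).pvalue)
    return {
        "classes": classes,
        "n": {c: int(len(groups[c])) for c in classes},
        "medians": {c: float(np.median(groups[c])) for c in classes},
        "pairwise": pairwise,
        "anova_p": anova_p,
    }


def overlap_stats(
    a_up: set, a_down: set, b_up: set, b_down: set, universe: int | None = None
) -> dict:
    """Direction-concordant overlap of two DE gene sets.

    Percentages are 100 * |concordant| / |A| rounded to the nearest integer
    for reporting, as in the study's text.  With a ``universe`` size, a
    hypergeometric enrichment p for the concordant overlap is included.
    """
    out = {}
    for direction, a, b in (("up", a_up, b_up), ("down", a_down, b_down)):
        conc = a & b
        entry: dict = {"n_a": len(a), "n_concordant": len(conc)}
        if a:
            entry["pct"] = round(100.0 * len(conc) / len(a))
        else:
            entry["pct"] = None
            entry["flag"] = "empty reference set"
        if universe is not None and a:
            # P(X >= |conc|) drawing |A| from universe with |B| successes
            entry["p_hyper"] = float(
                stats.hypergeom.sf(len(conc) - 1, universe, len(b), len(a))
            )
        out[direction] = entry
    return out
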