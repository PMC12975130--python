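"""Scalar cellular metrics: nuclear-signal kurtosis, smFISH copies per
cell, site allele frequency, and wound-healing migration/closure.

These are the defined per-cell and per-assay quantities downstream of
imaging or pileup steps; segmentation, spot detection and read piling are
upstream and out of scope here — the functions consume their tabular
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def nuclear_kurtosis(intensities) -> float:
    """Excess kurtosis g2 = m4/m2^2 - 3 of a nucleus' pixel intensities.

    Population (biased) moments, Fisher convention: 0 for a Gaussian.  A
    concentrated bright subcompartment against a diffuse background fattens
    the right tail and raises g2.  Requires n >= 4 and nonzero variance.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 4:
        raise ValueError("kurtosis needs at least 4 values")
    if not np.isfinite(x).all():
        raise ValueError("intensities must be finite")
    if np.var(x) == 0:
        raise ValueError("kurtosis undefined for zero-variance sample")
    return float(stats.kurtosis(x, fisher=True, bias=True))


def copies_per_cell(n_maxima, n_nuclei) -> float:
    """smFISH molecules per cell: detected maxima / DAPI-counted nuclei.

    Accepts scalars for one field or equal-length sequences for several;
    aggregation over fields pools totals (sum maxima / sum nuclei) rather
    than averaging per-field ratios.
    """
    maxima = int(np.sum(n_maxima))
    nuclei = int(np.sum(n_nuclei))
    if nuclei <= 0:
        raise ValueError("need a positive nucleus count")
    if maxima < 0:
        raise ValueError("negative maxima count")
    return maxima / nuclei


@dataclass(frozen=True)
class SiteBaseCounts:
    """Per-base read counts at one site, e.g. a position on 18S rRNA."""

    site: str
    counts: dict  # base -> count, bases A/C/G/T
    ref_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in self.counts:
            raise ValueError(f"reference base {self.ref_base} not in counts")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("base counts must be >= 0")

    @property
    def depth(self) -> int:
        return int(sum(self.counts.values()))


def allele_frequency(sbc: SiteBaseCounts, min_depth: int = 50):
    """Non-reference allele frequency at a site, or None below min depth.

    freq = (depth - ref count) / depth.  Sites under ``min_depth`` return
    ``None`` (flagged, no value) rather than an unreliable estimate.
    """
    depth = sbc.depth
    if depth < min_depth:
        return None
    return (depth - sbc.counts[sbc.ref_base]) / depth


def migration_rate(w_initial: float, w_t: float, t: float) -> float:
    """Cell migration rate R_M = (W_i - W_t) / t in um/h.

    Negative values mean the wound widened.
    """
    if t <= 0:
        raise ValueError("elapsed time must be positive")
    return (w_initial - w_t) / t


def wound_closure(a0: float, a_t: float) -> dict:
    """Wound closure fraction (A0 - At)/A0 and the normalized area At/A0."""
    if a0 <= 0:
        raise ValueError("initial wound area must be positive")
    closure = (a0 - a_t) / a0
    return {
        "closure": closure,
        "closure_pct": 100.0 * closure,
        "normalized_area": a_t / a0,
    }
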