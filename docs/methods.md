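# Methods

This note documents the models, defaults and design choices behind
`snhgpipe`, and what the synthetic benchmarks do and do not demonstrate.

## SNHG region partition

A host gene's region annotation is built from the exon union over all
annotated isoforms; the merged span minus that union gives the introns.
This union-merge is a deliberate choice: region classes must be disjoint
for counting, and a per-isoform annotation would double-count shared
bases. (A dominant-isoform alternative would be defensible; it is noted,
not implemented.)

Within a snoRNA-containing intron the snoRNA interval itself is `Snorna`;
the transcriptionally upstream remainder is `Pre` and the downstream
remainder `Post`, mirrored on the minus strand. When one intron carries
several snoRNAs, the gap between two of them is split at its midpoint so
that Pre/Post stay uniquely attributed to one snoRNA; the midpoint rounds
toward the transcriptionally downstream side, which makes coordinate
reflection plus strand flip an exact symmetry of the output (a property
the test suite enforces). A snoRNA overlapping the exon union violates
the scheme's premise (fully intronic snoRNAs); such hosts are excluded
with a diagnostic rather than reclassified.

All internal coordinates are 0-based half-open; GTF (1-based closed) and
BED conversions happen only in the I/O layer.

## Read assignment and normalization

Each read is credited to the single region class covering the majority of
its bases, with ties broken by `Snorna > Pre > Post > Exon > OtherIntron`
— the priority favors the shortest, biologically focal class. This
majority rule (rather than fractional assignment) keeps counts integral
and conserves the per-host total: region counts sum to the number of
host-overlapping reads, which the tests check against a brute-force
per-read oracle. Reads are treated as unstranded by default since library
strandedness is configuration, not biology.

Size factors are classical median-of-ratios: for features with nonzero
counts in every sample, factor_j = median_i(count_ij / geomean_i). Note
that scaling one sample by c changes every geometric mean by c^(1/n), so
the clean invariant is that factor *ratios* scale by c — the tests assert
that form. FPKM is count·10⁹/(length·total).

## Differential expression

The decision rule is the threshold pair padj < 0.05 and |log2FC| > 0.41
(2^0.41 − 1 ≈ 33% change), with features filtered below 5 mean normalized
counts or 200 nt of exonic length. The test behind the rule is kept
deliberately simple and transparent: a two-sided Welch t-test on
log2(normalized count + 1) with BH correction over tested features. This
replaces a negative-binomial GLM with dispersion shrinkage; the trade-off
is power at n = 3 (per-feature calls are conservative, as the worked
example in the README shows), in exchange for an easily calibrated
procedure — the suite verifies a ≤5% false-positive rate at padj < 0.05
on 100 seeded null simulations, and that planted ±0.5 log2 effects are
detected by the group-shift tests in ≥95 of 100 runs. The group-shift
machinery (pairwise Mann–Whitney, exact when the smaller group has ≤8
members, plus one-way ANOVA) is what the per-class figures rest on.

Degenerate features (zero variance in both groups, equal means) return
p = 1 by convention; zero variance with different means returns p = 0
(perfect separation). BH runs separately within each analysis (gene-level,
region-level, RIP), mirroring per-experiment testing.

## Cis/trans zoning and enrichment

A gene's position is its annotated TSS — regulation here is
promoter-centric — and "Cis" means the two TADs sharing the focal
boundary, not a distance radius. The digital cis test is a two-sided
Fisher exact test on {significant same-direction, not} × {Cis, elsewhere},
with a Haldane +0.5 odds-ratio correction for empty cells; the tests
check it against full hypergeometric tail enumeration. The contact
comparison is a Pearson chi-squared without continuity correction (df = 1)
on in-interval vs out-of-interval counts per condition; expected cells
below 1 attach a warning rather than failing.

## The screen

A (lncRNA, target) pair qualifies when the lncRNA gene span overlaps a
regulatory element with score ≥ `min_confidence` and both genes are
differentially expressed in the same condition. "High confidence" is a
numeric score threshold (the source database's own "elite" notion is not
reproduced). Direction concordance is required by default (matching the
final candidate set of such screens) but can be relaxed to the raw-screen
behavior with `require_concordance=False`, since the filter-versus-
prioritization placement of that requirement is genuinely ambiguous.
Candidates are ranked by supporting-condition count, then lncRNA
expression, with a lexicographic tie-break for determinism.

## Binding tiers

The composite binding score — Σ over peaks of signal × min(−log10 p, 10)
— is this package's concretization of "number, strength and confidence"
of binding sites; the cap stops a single extreme p value from dominating.
Bound genes are split into K = 4 rank-based quantile tiers (sizes differ
by ≤1 for distinct scores; ties collapse to the lower tier), tier 0 being
unbound. Expression-matched controls resample unbound genes to reproduce
each tier's expression-decile histogram with a fixed seed;
nearest-neighbor matching is not implemented. The trend readout is
Spearman's rho over (tier, log2FC) plus per-tier Mann–Whitney against
tier 0.

## Labeling kinetics

Continuous labeling with replenished 4sU justifies the first-order model:
new fraction f(t) = 1 − e^(−δt), half-life t½ = ln2/δ, and at steady
state σ = δ·abundance. Control fits minimize the weighted (by total
counts) squared error of observed new/total fractions over δ ∈
[ln2/100 h, ln2/0.1 h] with a bounded scalar solver (xatol 1e−12, so
noiseless curves are recovered to <1e−6 relative error; a dense grid
search over δ serves as the independent oracle in tests). Perturbed
samples drop the steady-state assumption and fit T(t) = T₀e^(−δt) +
(σ/δ)(1 − e^(−δt)) and N(t) = (σ/δ)(1 − e^(−δt)) jointly with free T₀.
Fits pinned at a δ bound, or with under 10% labeling by 24 h, are flagged
not-confident rather than dropped — very stable, short features (snoRNAs)
land here by construction, and their half-lives should not be
over-interpreted.

## Cellular metrics

Excess kurtosis uses population (biased) moments, Fisher convention
(g₂ = m₄/m₂² − 3): the estimator choice is not critical because the
metric is affine-invariant and only between-condition differences are
interpreted, but it is fixed and documented. Copies per cell pools across
imaging fields (total maxima / total nuclei) rather than averaging
per-field ratios, weighting each nucleus equally. Allele frequency is
(depth − ref)/depth with a 50-read depth floor below which no value is
returned. Wound metrics are the defining formulas: R_M = (W_i − W_t)/t
(negative = widening) and closure (A₀ − A_t)/A₀, with normalized area
A_t/A₀ so the two sum to one.

## The synthetic-data generator

The generator emulates the target study design: 3 knockdown vs 3 control
biological replicates; negative-binomial counts with variance μ + φμ²,
φ = 0.05 (typical bulk RNA-seq); planted effects as additive log2 offsets
on the knockdown mean, by channel (gene class, zone, SNHG region class,
binding tier); three chromosomes with genes laid out between intergenic
gaps; TADs as adjacent intervals with boundaries at gap midpoints and a
focal lncRNA starting exactly at one boundary; labeling time courses at
t = 0, 4, 8, 24 h with binomial new counts on Poisson totals (the
`depth=inf` sentinel yields exact noiseless values, used by the kinetics
closed-form tests), totals scaling with steady-state abundance so
synthesis-rate changes are observable; and per-nucleus pixel intensities
from a two-component log-normal mixture whose bright-component weight is
the ground truth behind the kurtosis ordering check. Every generator
draws from its own seeded substream, so outputs are byte-identical under
a fixed seed and stages can be regenerated independently.

Default problem sizes (500 genes, 25 SNHGs, 100-seed calibration loops,
200-feature kinetics cohorts at depth 200) were chosen so the full suite
and the acceptance script each complete in seconds to minutes on one CPU
while keeping the Monte-Carlo error of the calibration estimates well
below the asserted margins.

What the synthetic benchmarks show: that the implementations are
internally correct (oracle equivalence), calibrated under the null, and
powerful against the planted effect sizes at the study's replication
level. What they do not show: robustness to real-data features the
generator omits — isoform-level expression shifts, GC/length biases,
batch effects, correlated genes, mappability artifacts, or
conversion-calling errors upstream of the kinetics counts. Claims about
real datasets require the usual upstream QC.

## Known limitations

- The DE procedure trades per-feature power for transparency at low n;
  group-level statistics are the intended readout.
- The kinetics module consumes new/total counts; it does not model the
  T>C conversion process that produces them upstream.
- The screen's regulatory-element map is taken as given; no enhancer
  evidence is re-derived.
- TAD structure is an input; no TAD calling from contact data.
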