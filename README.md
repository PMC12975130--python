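# snhgpipe

Region-resolved quantification of snoRNA host genes and cis/trans effect
analysis for lncRNA perturbation studies.

Many long noncoding RNAs are snoRNA host genes (SNHGs): spliced transcripts
whose introns carry small nucleolar RNAs that are released during splicing.
When such a lncRNA is knocked down, the interesting biology is *where* the
change happens — in the spliced exons, in the intronic sequence immediately
upstream (Pre) or downstream (Post) of the embedded snoRNA, in snoRNA-less
introns, or in the snoRNA itself — and *where in the genome* the downstream
effects land: in the two TADs flanking the lncRNA's own boundary (cis), on
the same chromosome, or genome-wide (trans). `snhgpipe` implements this
analysis end to end, together with the companion computations such studies
rely on: a candidate cis-lncRNA screen, binding-confidence tiering with
expression-matched controls, first-order metabolic-labeling kinetics, and
defined cellular metrics (nuclear-signal kurtosis, smFISH copies per cell,
site allele frequency, wound-healing rates).

Everything runs on synthetic data with known ground truth, generated by the
package itself, so every stage is testable without external downloads.

## The core computations

**SNHG partition.** For each host gene, exons are unioned over isoforms;
introns are the merged span minus the exon union. A snoRNA-containing
intron is cut at the snoRNA boundaries into Pre (transcriptionally upstream)
and Post (downstream); snoRNA-free introns are OtherIntron. Reads are then
assigned per region by majority overlap, with ties broken
Snorna > Pre > Post > Exon > OtherIntron.

**Differential expression.** Median-of-ratios size factors, fold change
log2((mean_kd + 1)/(mean_ctrl + 1)) on normalized counts, a two-sided Welch
t-test on log2(normalized + 1), Benjamini–Hochberg correction, and the
decision rule padj < 0.05 and |log2FC| > 0.41 (a ~33% change), after
filtering features under 5 mean normalized counts or 200 nt of exonic
length. Group-level shifts use Mann–Whitney tests (exact for small groups)
plus a global one-way ANOVA.

**Cis/trans zoning.** Genes are classed by TSS: inside either TAD flanking
the focal boundary → Cis; same chromosome → SameChromosome; else Trans.
Cis action is tested as a Fisher-exact enrichment of significant
same-direction genes in the Cis zone, and 4C-style contact counts over a
quantified interval are compared between conditions with a df=1 Pearson
chi-squared test.

**Labeling kinetics.** Under continuous 4sU labeling the new fraction of a
transcript with decay rate δ follows f(t) = 1 − e^(−δt); half-life is
t½ = ln2/δ and the synthesis rate σ = δ·abundance at steady state. Control
samples are fitted under the steady-state assumption; perturbed samples
jointly on total and new levels without it.

## Worked example

The numbered drivers under `analysis/` run the full synthetic study
(seed 1: 500 genes, 25 SNHGs, 3 vs 3 replicates, +0.5 log2 on
snoRNA-proximal regions and −0.5 on Cis-zone genes in the knockdown):

```
cd analysis
python 03_differential.py
```

prints

```
gene-level DE: 0 up, 0 down, 501 ns, 0 filtered
region-level DE: 0 up, 0 down, 155 ns, 50 filtered
Median log2FC by region class (ANOVA p = 3.32e-17):
  Exon: -0.204
  OtherIntron: -0.095
  Post: +0.232
  Pre: +0.197
  Snorna: +0.310
```

The planted snoRNA-proximal upshift is visible as a group (Snorna/Pre/Post
medians above the Exon/OtherIntron baseline, ANOVA p ≈ 3e-17) even though
no single region clears the per-feature threshold at n = 3 — the group
statistics, not individual calls, carry the signal at this replication
level. Likewise `python 04_cis_trans.py` shows the Cis-zone median at
−0.497 (truth −0.5) against ~0 elsewhere, and `python 07_kinetics.py`
recovers the planted synthesis-rate halving (median Δlog2σ = −0.98,
truth −1.0, median half-life error 4.4%).

A thin CLI wraps the same stages (`snhgpipe run --outdir out --seed 1`).

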