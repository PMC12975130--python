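import numpy as np
import pytest

from snhgpipe.simulate import SimConfig, gen_annotation


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=1, n_genes=100, n_snhgs=10)


@pytest.fixture(scope="session")
def small_annotation(small_cfg):
    return gen_annotation(small_cfg)


def random_gene_model(rng: np.random.Generator, gene_id: str = "G"):
    """A random small gene model (<=5 isoforms, span <= 10 kb) plus
    snoRNAs placed in random merged introns, for oracle-based checks."""
    from snhgpipe.partition import GeneModel, SnoRecord, merge_intervals

    strand = "+" if rng.random() < 0.5 else "-"
    n_iso = int(rng.integers(1, 6))
    isoforms = []
    for _ in range(n_iso):
        n_ex = int(rng.integers(1, 5))
        cuts = np.sort(rng.choice(np.arange(0, 10_000, 10), 2 * n_ex,
                                  replace=False))
        exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1]))
                 for i in range(n_ex)]
        isoforms.append(tuple(exons))
    model = GeneModel(gene_id, "chrT", strand, tuple(isoforms))

    # candidate snoRNAs inside merged introns
    span = model.span
    exon_union = merge_intervals(model.exon_union())
    introns = []
    cur = span[0]
    for s, e in exon_union:
        if s > cur:
            introns.append((cur, s))
        cur = max(cur, e)
    snos = []
    k = 0
    for lo, hi in introns:
        if hi - lo < 40 or rng.random() < 0.4:
            continue
        n_in = int(rng.integers(1, 3))
        width = (hi - lo) // (n_in * 4)
        for j in range(n_in):
            seg_lo = lo + j * (hi - lo) // n_in
            s = seg_lo + width
            e = s + max(width, 5)
            if e < lo + (j + 1) * (hi - lo) // n_in:
                snos.append(SnoRecord(f"S{k}", gene_id, s, e))
                k += 1
    return model, snos


def per_base_oracle(model, snos) -> dict[int, tuple[str, str | None]]:
    """Label every base of the merged span by the partition merge rules.

    Brute force: exon-union bases are Exon; intron bases inside a snoRNA
    are Snorna; other intron bases in a snoRNA-containing intron belong to
    the nearest snoRNA (gaps between two snoRNAs split at the midpoint)
    and are Pre if transcriptionally upstream of it, else Post; introns
    without snoRNAs are OtherIntron.
    """
    span = model.span
    exonic = set()
    for iso in model.isoforms:
        for s, e in iso:
            exonic.update(range(s, e))
    labels: dict[int, tuple[str, str | None]] = {}
    plus = model.strand == "+"
    # merged introns
    intron_bases = [b for b in range(*span) if b not in exonic]
    # group into maximal runs
    runs = []
    for b in intron_bases:
        if runs and b == runs[-1][1]:
            runs[-1][1] = b + 1
        else:
            runs.append([b, b + 1])
    for b in exonic:
        if span[0] <= b < span[1]:
            labels[b] = ("Exon", None)
    for lo, hi in runs:
        inside = sorted([s for s in snos if lo <= s.start and s.end <= hi],
                        key=lambda s: s.start)
        if not inside:
            for b in range(lo, hi):
                labels[b] = ("OtherIntron", None)
            continue
        for b in range(lo, hi):
            owner = None
            for s in inside:
                if s.start <= b < s.end:
                    owner = (s, "in")
                    break
            if owner is None:
                # nearest snoRNA with midpoint splits; ties go to the
                # transcriptionally downstream snoRNA (its Pre side)
                pre_side = "left" if plus else "right"
                best = None
                for s in inside:
                    if b < s.start:
                        d = s.start - b
                        side = "left"
                    else:
                        d = b - s.end + 1
                        side = "right"
                    if best is None or d < best[0] or (
                        d == best[0] and side == pre_side
                    ):
                        best = (d, side, s)
                _, side, s = best
                if side == "left":
                    cls = "Pre" if plus else "Post"
                else:
                    cls = "Post" if plus else "Pre"
                labels[b] = (cls, s.sno_id)
            else:
                labels[b] = ("Snorna", owner[0].sno_id)
    return labels
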