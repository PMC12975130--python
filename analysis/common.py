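"""Shared study configuration for the numbered analysis drivers.

One synthetic "study": 500 genes on 3 chromosomes, 25 snoRNA host genes,
a focal lncRNA at a TAD boundary, 3 knockdown vs 3 control replicates,
NB dispersion 0.05.  The knockdown raises the snoRNA-proximal intronic
regions (+0.5 log2) — the signature of impaired snoRNA-host processing —
and lowers genes in the two TADs flanking the focal boundary (-0.5 log2),
the cis signature.
"""

from pathlib import Path

from snhgpipe.pipeline import PipelineConfig
from snhgpipe.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"

STUDY_EFFECTS = {
    "region:Snorna": 0.5,
    "region:Pre": 0.5,
    "region:Post": 0.5,
    "zone:Cis": -0.5,
}


def study_config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(
        outdir=RESULTS,
        sim=SimConfig(seed=seed, n_genes=500, n_snhgs=25,
                      effects=STUDY_EFFECTS),
        kinetics_n_features=200,
        kinetics_depth=200.0,
    )
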