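"""Partition every SNHG into Exon/Pre/Snorna/Post/OtherIntron regions
and normalize the region-level counts (size factors, FPKM).
"""

from common import study_config

from snhgpipe.pipeline import run_pipeline

report = run_pipeline(study_config(),
                      ["simulate", "partition", "quantify"])
p = report["stages"]["partition"]
q = report["stages"]["quantify"]
print(f"Partitioned {p['n_partitions']} snoRNA host genes into "
      f"{q['n_regions']} disjoint regions "
      f"({len(p['diagnostics'])} hosts excluded).")
print("Median-of-ratios size factors per sample:")
for sample, factor in q["size_factors"].items():
    print(f"  {sample}: {factor}")
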