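"""AZ-array probe design, specificity screening and layout accounting.

Designs sense+antisense 60-mers (annotated: 1+1, novel: 2+2), screens
them for cross-hybridization against the full transcript set — the
duplicate pair is flagged — and fills a small array to capacity.

Also reproduces the published array accounting from its category sizes.
"""

from collections import Counter

from azkit.probes import allocation_summary, build_layout, design_probes, layout_accounting
from azkit.synth import SimConfig, generate_truth

cfg = SimConfig(seed=6, n_known=12, n_novel=4, n_contaminant=0, n_duplicated=1)
truth = generate_truth(cfg)
transcripts = {t: s for t, s in truth.transcripts.items()}
categories = {t: ("novel" if truth.categories[t] == "novel" else "annotated") for t in transcripts}

probes = design_probes(transcripts, categories)
print("probe classes:", dict(Counter(p.probe_class for p in probes)))
layout, final = build_layout(probes, capacity=120, control_features=6)
print(f"array: {layout.total_probes} probes + {layout.control_features} controls "
      f"= {layout.total_features} features ({layout.filler_duplicates} filler duplicates)")

# The published 4x180K accounting, recomputed from its inputs:
alloc = allocation_summary({"annotated": 31298, "novel": 8823, "cross_species": 838, "legacy": 356})
big = layout_accounting(designed=93674, qc_probes=200, vendor_probes=2278,
                        control_features=4854, capacity=180880)
print(f"published-scale: {alloc['total_probes']} initial probes for "
      f"{alloc['array_transcripts']} transcripts; final array "
      f"{big.total_probes} probes / {big.total_features} features")

# cross_hyb probes come from the near-identical duplicate pair: both copies
# align the same 60-mer window within the screen's <3 mismatch / <2 gap bounds.
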