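"""Localize a TBP-sized footprint with short-fragment TSS profiles.

Restricting to fragments of at most 80 bp isolates single-binding-event
cleavages; the CPM-normalized average profile over a 2 kb TSS-centred
window then peaks at the true binding offset.
"""

import numpy as np

from medtail import SimConfig, simulate_annotation, simulate_fragments, size_filtered_profile

cfg = SimConfig(seed=8, n_genes_exp=150, n_genes_spike=10, n_fragments=30_000)
ann = simulate_annotation(cfg)
exp = ann[ann["organism"] == "experimental"]
frags = simulate_fragments(ann, cfg, "tbp_like").fragments

prof = size_filtered_profile(frags, exp, cfg.chrom_sizes, max_len=80, flank=1000, bin_size=10)
peak = prof.positions[np.argmax(prof.values)]
print(f"{prof.n_fragments_used} fragments <= 80 bp over {prof.n_genes} genes")
print(f"profile peak at {peak:+.0f} bp from the TSS (simulated footprint at {cfg.tbp_offset} bp)")
print(f"peak {prof.values.max():.0f} CPM vs distal flank {prof.values[:20].mean():.2f} CPM")
# The argmax bin sits within one or two bins of the simulated binding site;
# distal flanks carry essentially no short-fragment signal.
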