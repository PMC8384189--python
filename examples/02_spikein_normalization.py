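"""Estimate per-sample size factors from spike-in genes.

Median-of-ratios on the spike-in count block recovers each library's depth
factor; applying those factors to the experimental genes puts all samples on
a common absolute scale even if the perturbation shifts global transcription.
"""

import numpy as np

from medtail import SimConfig, apply_size_factors, simulate_annotation, simulate_counts, size_factors_median_of_ratios

depths = np.array([0.6, 1.0, 1.4, 0.8, 1.2, 1.6])
cfg = SimConfig(seed=2, n_genes_exp=100, n_genes_spike=50, depth_factors=depths)
ann = simulate_annotation(cfg)
sim = simulate_counts(ann, cfg)

spike_ids = ann.loc[ann["organism"] == "spikein", "gene_id"]
sf = size_factors_median_of_ratios(sim.counts.loc[spike_ids])
print("true depth factors:", depths.round(3).tolist())
print("estimated sf:      ", sf.factors.round(3).tolist(), f"({sf.n_genes_used} spike-in genes)")
# The two vectors agree up to an arbitrary common constant: size factors are
# defined only up to scale, and the DE test is invariant to that constant.
norm = apply_size_factors(sim.counts.loc[spike_ids], sf)
print("normalized spike-in column means:", norm.mean(axis=0).round(1).tolist())
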