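"""Generate a complete synthetic dataset with ground truth.

Writes annotation, NB counts for two conditions (3 replicates each) with a
1:4-style spike-in, three kinds of cleavage-fragment libraries, and the
ground-truth tables (true log2 fold changes, depth factors, UAS windows).
"""

import pandas as pd

from medtail import SimConfig, write_dataset

cfg = SimConfig(seed=1, n_genes_exp=300, n_genes_spike=50, n_fragments=20_000)
paths = write_dataset("scratch/example_dataset", cfg)

truth = pd.read_csv(paths["truth_genes"], sep="\t")
n_reg = (truth["true_log2fc"] != 0).sum()
print(f"wrote {len(paths)} files under scratch/example_dataset/")
print(f"{len(truth)} genes total, {n_reg} with a true fold change "
      f"(mean |lfc| {truth.loc[truth.true_log2fc != 0, 'true_log2fc'].abs().mean():.2f})")
# The regulated genes are concentrated in CR (down) and TFIID-dependent (up)
# classes; the spike-in genes all have lfc = 0 and anchor the normalization.
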