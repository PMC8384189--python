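"""Spike-in normalization: median-of-ratios size factors and ChEC scale factors.

Size factors are estimated on spike-in genes only and then applied to the
experimental genes of the same libraries, so between-sample comparisons are
anchored to the fixed-composition spike-in rather than to total signal —
essential when a perturbation shifts global transcription.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SizeFactors:
    """Per-sample size factors and the number of spike-in genes that fed them."""

    factors: pd.Series  # index: sample ids; values > 0
    n_genes_used: int

    def __post_init__(self):
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise ValueError("size factors must be positive and finite")
        if self.n_genes_used < 1:
            raise ValueError("n_genes_used must be >= 1")


def size_factors_median_of_ratios(spike_counts: pd.DataFrame) -> SizeFactors:
    """Median-of-ratios size factors from a spike-in count matrix.

    For each gene i with positive geometric mean g_i = (prod_j k_ij)^(1/m),
    sf_j = median_i k_ij / g_i. Genes with any zero count have g_i = 0 and
    are excluded (no pseudocount). Raises ``ValueError`` if no gene is
    usable.
    """
    counts = spike_counts.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no spike-in gene with positive geometric mean")
    k = counts[usable]
    log_g = np.log(k).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(k) - log_g)  # k_ij / g_i, computed in log space
    sf = np.median(ratios, axis=0)
    factors = pd.Series(sf, index=spike_counts.columns, name="size_factor")
    return SizeFactors(factors=factors, n_genes_used=int(usable.sum()))


def apply_size_factors(counts: pd.DataFrame, sf: SizeFactors | pd.Series, drop_spike_prefix: str | None = None) -> pd.DataFrame:
    """Divide each sample column by its size factor.

    Sample ids must match exactly. With ``drop_spike_prefix`` set, gene rows
    whose chromosome-style id starts with the prefix are dropped from the
    result.
    """
    factors = sf.factors if isinstance(sf, SizeFactors) else sf
    missing = set(counts.columns) ^ set(factors.index)
    if missing:
        raise ValueError(f"sample ids do not match size factors: {sorted(missing)}")
    norm = counts / factors.reindex(counts.columns)
    if drop_spike_prefix is not None:
        norm = norm.loc[~norm.index.str.startswith(drop_spike_prefix)]
    return norm


def chec_scale_factors(spike_fragment_counts: pd.Series) -> pd.Series:
    """Spike-in scale factors for ChEC coverage tracks.

    scale_j is proportional to 1 / (spike-in fragment count of sample j),
    with the constant fixed so the mean scale across samples is 1. Raises
    ``ValueError`` naming any sample without spike-in fragments.
    """
    counts = spike_fragment_counts.astype(float)
    zero = counts.index[counts <= 0].tolist()
    if zero:
        raise ValueError(f"no spike-in fragments in sample(s): {zero}")
    raw = 1.0 / counts
    scale = raw / raw.mean()
    scale.name = "scale_factor"
    return scale


def count_spike_fragments(fragments_by_sample: dict[str, pd.DataFrame], spike_prefix: str = "spike_") -> pd.Series:
    """Count fragments assigned to spike-in chromosomes per sample."""
    return pd.Series(
        {sid: int(frags["chrom"].str.startswith(spike_prefix).sum()) for sid, frags in fragments_by_sample.items()}
    )
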