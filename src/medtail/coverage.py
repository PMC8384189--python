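"""Fragment coverage tracks, upstream/TESR enrichment scores, and TSS profiles.

The scoring strategy is within-sample: for each gene, signal in the 500 bp
window upstream of the TSS (where UAS-bound factors cut) is divided by
signal in the 500 bp window centred on the TES (nucleosome-depleted but not
factor-bound), so a change in overall cutting efficiency or free-MNase
background cancels out of the ratio. Group contrasts on these log2 ratios
use the Wilcoxon rank-sum test. TBP-footprint analysis restricts to short
(<=80 bp) fragments and averages CPM signal in a 2 kb window centred on the
TSS, oriented so upstream is to the left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SignalTrack:
    """Binned, normalized coverage: one value per ``bin_size`` bp bin per chrom."""

    values: dict[str, np.ndarray]
    bin_size: int
    chrom_sizes: dict[str, int]
    tag: str = "raw"  # per-million | spike-scaled | CPM | raw

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def fragment_coverage(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_size: int = 10,
    normalization: str = "per-million",
    scale: float | None = None,
) -> SignalTrack:
    """Full-span fragment pileup, binned and normalized.

    Each fragment adds 1 to every bp of its span; bins carry the mean per-bp
    coverage within the bin. ``per-million`` / ``CPM`` rescale so the total
    fragment count maps to 1e6 (each fragment contributes weight 1e6/N);
    ``spike-scaled`` multiplies raw coverage by the supplied spike-in scale
    factor; ``none`` leaves raw counts. Fragments beyond a chromosome end
    are clipped (warning reports the count); fragments on chromosomes absent
    from ``chrom_sizes`` raise.
    """
    if normalization not in ("per-million", "CPM", "spike-scaled", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization == "spike-scaled" and scale is None:
        raise ValueError("spike-scaled normalization requires a scale factor")
    n_frags = len(fragments)
    if normalization in ("per-million", "CPM"):
        if n_frags == 0:
            warnings.warn("empty fragment set: normalization skipped, returning zero track")
            factor = 1.0
        else:
            factor = 1e6 / n_frags
    elif normalization == "spike-scaled":
        factor = float(scale)
    else:
        factor = 1.0

    unknown = set(fragments["chrom"].unique()) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"fragments on chromosomes missing from chrom_sizes: {sorted(unknown)}")

    values = {}
    n_clipped = 0
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_size)
        diff = np.zeros(n_bins * bin_size + 1)
        sub = fragments[fragments["chrom"] == chrom]
        if len(sub):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            n_clipped += int(((starts < 0) | (ends > size)).sum())
            starts = np.clip(starts, 0, size)
            ends = np.clip(ends, 0, size)
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
        per_bp = np.cumsum(diff[:-1]) * factor
        values[chrom] = per_bp.reshape(n_bins, bin_size).mean(axis=1)
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} fragments at chromosome ends")
    return SignalTrack(values=values, bin_size=bin_size, chrom_sizes=dict(chrom_sizes), tag=normalization)


def window_signal(track: SignalTrack, chrom: str, start: int, end: int) -> float:
    """Sum of bin values over [start, end), partial bins weighted by overlap.

    A window spanning w full bins of a uniform track with value v returns
    v * w. Windows are clipped to the chromosome; an unknown chromosome
    raises ``KeyError``.
    """
    if chrom not in track.values:
        raise KeyError(f"unknown chromosome {chrom!r}")
    vals = track.values[chrom]
    b = track.bin_size
    start = max(int(start), 0)
    end = min(int(end), len(vals) * b)
    if end <= start:
        return 0.0
    first, last = start // b, (end - 1) // b
    if first == last:
        return float(vals[first] * (end - start) / b)
    total = vals[first] * ((first + 1) * b - start) / b
    total += vals[last] * (end - last * b) / b
    if last > first + 1:
        total += vals[first + 1 : last].sum()
    return float(total)


def upstream_tesr_scores(
    track: SignalTrack,
    annotation: pd.DataFrame,
    upstream_len: int = 500,
    tesr_len: int = 500,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene upstream vs TES-region enrichment on a signal track.

    Upstream window: [TSS-upstream_len, TSS) for + genes, (TSS, TSS+upstream_len]
    for - genes. TES region: [TES - tesr_len/2, TES + tesr_len/2), with TES the
    strandwise 3' end. log2_ratio = log2((upstream+pc)/(tesr+pc)); windows that
    had to be clipped at a chromosome edge are flagged.
    """
    rows = []
    half = tesr_len // 2
    for gene in annotation.itertuples(index=False):
        chrom = gene.chrom
        size = track.chrom_sizes[chrom]
        if gene.strand == "+":
            u0, u1 = gene.tss - upstream_len, gene.tss
        else:
            u0, u1 = gene.tss + 1, gene.tss + 1 + upstream_len
        t0, t1 = gene.tes - half, gene.tes - half + tesr_len
        clipped = u0 < 0 or t0 < 0 or u1 > size or t1 > size
        up = window_signal(track, chrom, u0, u1)
        te = window_signal(track, chrom, t0, t1)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "upstream_signal": up,
                "tesr_signal": te,
                "log2_ratio": np.log2((up + pseudocount) / (te + pseudocount)),
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def compare_groups(scores_a, scores_b, exact_max_n: int = 8) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two score groups.

    Uses the exact null distribution when both groups have <= ``exact_max_n``
    values and no ties straddle groups, the tie-corrected normal
    approximation otherwise (scipy's automatic policy matches this choice).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    method = "exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "n_a": len(a), "n_b": len(b), "method": method}


def compare_groups_pairwise(groups: dict[str, "np.ndarray"]) -> pd.DataFrame:
    """All pairwise rank-sum tests with Holm correction across the pairs."""
    names = list(groups)
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            res = compare_groups(groups[gi], groups[gj])
            rows.append({"group_a": gi, "group_b": gj, "statistic": res["statistic"], "p_value": res["p_value"]})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = multipletests(out["p_value"].to_numpy(), method="holm")[1]
    return out


@dataclass
class ProfileResult:
    positions: np.ndarray  # bin-centre offsets relative to the TSS (bp)
    values: np.ndarray  # mean normalized signal per bin over the gene group
    n_genes: int
    n_fragments_used: int
    per_gene: np.ndarray = field(repr=False, default=None)  # genes x bins matrix


def size_filtered_profile(
    fragments: pd.DataFrame,
    annotation: pd.DataFrame,
    chrom_sizes: dict[str, int],
    max_len: int = 80,
    flank: int = 1000,
    bin_size: int = 10,
    ignore_duplicates: bool = True,
    genes: set | None = None,
) -> ProfileResult:
    """TSS-centred average profile of size-selected fragments.

    Retains fragments with length <= ``max_len`` (optionally dropping exact
    (chrom, start, end) duplicates), CPM-normalizes their full-span coverage,
    extracts the 2*flank window centred on each gene's TSS oriented so
    upstream lies to the left, and averages across the gene group per bin.
    An empty post-filter fragment set yields an all-zero profile with a
    warning.
    """
    lengths = fragments["end"] - fragments["start"]
    kept = fragments[lengths <= max_len]
    if ignore_duplicates:
        kept = kept.drop_duplicates(subset=["chrom", "start", "end"])
    n_used = len(kept)
    n_bins = 2 * flank // bin_size
    ann = annotation if genes is None else annotation[annotation["gene_id"].isin(genes)]
    positions = (np.arange(n_bins) + 0.5) * bin_size - flank
    if n_used == 0:
        warnings.warn("no fragments pass the size filter: returning zero profile")
        zero = np.zeros(n_bins)
        return ProfileResult(positions, zero, len(ann), 0, np.zeros((len(ann), n_bins)))

    track = fragment_coverage(kept, chrom_sizes, bin_size=bin_size, normalization="CPM")
    mat = np.zeros((len(ann), n_bins))
    for row, gene in enumerate(ann.itertuples(index=False)):
        vals = track.values[gene.chrom]
        centre_bin = gene.tss // bin_size
        lo = centre_bin - n_bins // 2
        hi = lo + n_bins
        window = np.zeros(n_bins)
        src_lo, src_hi = max(lo, 0), min(hi, len(vals))
        window[src_lo - lo : src_hi - lo] = vals[src_lo:src_hi]
        if gene.strand == "-":
            window = window[::-1]
        mat[row] = window
    return ProfileResult(positions, mat.mean(axis=0), len(ann), n_used, mat)
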