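"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: all genomic coordinates are 0-based half-open, matching BED.
Annotation travels as BED6 plus a sidecar TSV carrying organism / class /
TATA labels; counts and per-gene result tables are TSV with a header row.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "organism", "gene_class", "tata"]
FRAGMENT_COLUMNS = ["chrom", "start", "end"]


def write_annotation(annotation: pd.DataFrame, bed_path: str, labels_path: str) -> None:
    """Write gene annotation as BED6 plus a label sidecar TSV."""
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["start"],
            "end": annotation["end"],
            "name": annotation["gene_id"],
            "score": 0,
            "strand": annotation["strand"],
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    labels = annotation[["gene_id", "organism", "gene_class", "tata"]].copy()
    labels["tata"] = labels["tata"].astype(int)
    labels.to_csv(labels_path, sep="\t", index=False)


def read_annotation(bed_path: str, labels_path: str | None = None) -> pd.DataFrame:
    """Read a BED6 annotation (and optional label sidecar) into a DataFrame."""
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "gene_id": str, "strand": str},
    )
    ann = bed[["gene_id", "chrom", "start", "end", "strand"]].copy()
    if labels_path is not None:
        labels = pd.read_csv(labels_path, sep="\t", dtype={"gene_id": str})
        labels["tata"] = labels["tata"].astype(bool)
        ann = ann.merge(labels, on="gene_id", how="left")
    else:
        ann["organism"] = "experimental"
        ann["gene_class"] = "unannotated"
        ann["tata"] = False
    return add_tss_tes(ann)


def add_tss_tes(annotation: pd.DataFrame) -> pd.DataFrame:
    """Attach strand-aware TSS/TES columns (TSS=start for +, end-1 for -)."""
    ann = annotation.copy()
    plus = ann["strand"] == "+"
    ann["tss"] = np.where(plus, ann["start"], ann["end"] - 1)
    ann["tes"] = np.where(plus, ann["end"] - 1, ann["start"])
    return ann


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_samples(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})


def write_fragments_bed(fragments: pd.DataFrame, path: str) -> None:
    """Write fragment spans as 3-column BED."""
    fragments[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path: str) -> pd.DataFrame:
    frags = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=FRAGMENT_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return frags


def write_fragments_bedpe(fragments: pd.DataFrame, path: str, read_len: int = 50) -> None:
    """Write fragments as BEDPE mate pairs.

    Mate 1 covers the first `read_len` bp of the fragment span and mate 2 the
    last `read_len` bp (shorter fragments yield fully overlapping mates),
    which is how a paired-end library over these spans would align.
    """
    length = fragments["end"] - fragments["start"]
    rl = np.minimum(read_len, length)
    bedpe = pd.DataFrame(
        {
            "chrom1": fragments["chrom"],
            "start1": fragments["start"],
            "end1": fragments["start"] + rl,
            "chrom2": fragments["chrom"],
            "start2": fragments["end"] - rl,
            "end2": fragments["end"],
            "name": [f"frag{i}" for i in range(len(fragments))],
            "score": 0,
            "strand1": "+",
            "strand2": "-",
        }
    )
    bedpe.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bedpe(path: str) -> pd.DataFrame:
    """Read BEDPE and reduce each mate pair to its full fragment span."""
    bedpe = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 5], names=["chrom", "start", "end"], dtype={0: str})
    return bedpe


def write_size_factors(factors: pd.Series, n_genes_used: int, path: str) -> None:
    out = pd.DataFrame({"sample_id": factors.index, "size_factor": factors.values})
    out["n_genes_used"] = n_genes_used
    out.to_csv(path, sep="\t", index=False)


def read_size_factors(path: str) -> pd.Series:
    tab = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return pd.Series(tab["size_factor"].values, index=tab["sample_id"].values, name="size_factor")


def write_de_table(de: pd.DataFrame, path: str) -> None:
    de.to_csv(path, sep="\t", index_label="gene_id")


def read_de_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_bedgraph(track, path: str) -> None:
    """Write a binned signal track as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            size = track.chrom_sizes[chrom]
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change]) * track.bin_size
            ends = np.concatenate([change, [len(vals)]]) * track.bin_size
            ends = np.minimum(ends, size)
            for s, e, v in zip(starts, ends, vals[np.concatenate([[0], change])]):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str, chrom_sizes: dict[str, int], bin_size: int = 10):
    """Read a bedGraph into a binned SignalTrack (values averaged per bin)."""
    from .coverage import SignalTrack

    tab = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"], dtype={"chrom": str})
    values = {}
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_size)
        per_bp = np.zeros(n_bins * bin_size)
        sub = tab[tab["chrom"] == chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            per_bp[s:e] = v
        values[chrom] = per_bp.reshape(n_bins, bin_size).mean(axis=1)
    return SignalTrack(values=values, bin_size=bin_size, chrom_sizes=dict(chrom_sizes), tag="bedgraph")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
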