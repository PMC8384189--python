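"""Synthetic nascent-RNA count and ChEC cleavage-fragment generator.

Emulates the structure of a spike-in-normalized yeast transcription study:
negative-binomial gene counts with per-sample depth factors and a
fixed-composition spike-in genome (cells mixed at roughly 1:4 spike-in to
experimental, giving ~20% spike-in material), true log2 fold changes
concentrated in a coactivator-redundant-down / TFIID-up pattern, and
paired-end cleavage fragments with factor peaks over upstream activating
sequences (UASs), elevated free-MNase background over nucleosome-depleted
transcription-end regions, and a bimodal fragment-length mixture whose short
mode (<=80 bp) carries the TBP-footprint signal.

Every draw is keyed off one integer seed expanded into independent child
streams per (stage, sample), so adding a sample never perturbs earlier ones.
Ground truth (true lfc, depth factors, UAS windows) is always emitted
alongside the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import io as mio

logger = logging.getLogger(__name__)

SPIKE_PREFIX = "spike_"
FACTORS = ("bound_factor", "free_mnase", "tbp_like")

# fixed stream ids so child seeds are stable across code reorganisation
_STREAM = {"annotation": 1, "params": 2, "counts": 3, "fragments": 4}


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Per-gene parameter arrays (``base_abundance``, ``true_log2fc``,
    ``dispersion``) and per-sample ``depth_factors`` may be supplied
    explicitly; when left ``None`` they are realized deterministically from
    the seed (see :func:`realize_parameters`).
    """

    seed: int = 0
    n_genes_exp: int = 400
    n_genes_spike: int = 60
    chrom_sizes: dict = field(
        default_factory=lambda: {"chrI": 800_000, "chrII": 800_000, f"{SPIKE_PREFIX}I": 300_000}
    )
    conditions: tuple = ("control", "depleted")
    replicates_per_condition: int = 3
    base_abundance: np.ndarray | None = None  # q_i, per gene
    true_log2fc: np.ndarray | None = None  # lfc_i, per gene (0 for spike-in)
    dispersion: float | np.ndarray = 0.05  # alpha_i; scalar broadcast per gene
    depth_factors: np.ndarray | None = None  # d_j, per sample
    depth_factor_sd: float = 0.25  # log-normal sd used when d_j not supplied
    spikein_fraction: float = 0.2  # fragment share on spike-in chroms (1:4 mix)
    # gene-class composition and regulation pattern
    class_fractions: dict = field(default_factory=lambda: {"CR": 0.2, "TFIID": 0.6, "unannotated": 0.2})
    frac_regulated_cr: float = 0.6  # CR genes predominantly down-regulated
    frac_regulated_tfiid: float = 0.4  # TFIID genes modestly up-regulated
    # fragment model
    n_fragments: int = 50_000
    uas_offset: int = 200  # bp upstream of TSS to the UAS window centre
    uas_width: int = 100
    uas_signal_weight: float = 0.7  # share of bound-factor cuts inside UASs
    tes_background_boost: float = 3.0
    tbp_offset: int = -60  # TBP footprint midpoint relative to TSS (strandwise)
    tbp_jitter_sd: float = 8.0
    # (weight, mean, sd, min_len, max_len) per mode; first mode must be <=80 bp
    fraglen_mix: tuple = ((0.35, 60.0, 10.0, 20, 80), (0.65, 150.0, 25.0, 81, 250))
    gene_length_range: tuple = (500, 2000)
    min_flank: int = 1000

    def __post_init__(self):
        for name in ("spikein_fraction", "uas_signal_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ValueError("dispersion must be non-negative")
        if self.tes_background_boost <= 0:
            raise ValueError("tes_background_boost must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{c}_rep{r + 1}" for c in self.conditions for r in range(self.replicates_per_condition)]

    @property
    def sample_conditions(self) -> list[str]:
        return [c for c in self.conditions for _ in range(self.replicates_per_condition)]

    def rng(self, stage: str, *key: int) -> np.random.Generator:
        """Child generator for one stream, stable under stream addition."""
        ss = np.random.SeedSequence([int(self.seed), _STREAM[stage], *[int(k) for k in key]])
        return np.random.Generator(np.random.PCG64(ss))

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        if "fraglen_mix" in raw:
            raw["fraglen_mix"] = tuple(tuple(m) for m in raw["fraglen_mix"])
        if "gene_length_range" in raw:
            raw["gene_length_range"] = tuple(raw["gene_length_range"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
            elif isinstance(v, tuple):
                d[k] = [list(x) if isinstance(x, tuple) else x for x in v]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def is_spike_chrom(chrom: str) -> bool:
    return chrom.startswith(SPIKE_PREFIX)


def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Place non-overlapping genes on experimental and spike-in chromosomes.

    Genes get random lengths within ``gene_length_range``, at least
    ``min_flank`` bp between neighbours, random strands, and class labels
    drawn from ``class_fractions`` (spike-in genes are all unannotated).
    Raises ``ValueError`` naming the chromosome if the requested genes
    cannot be packed.
    """
    rng = config.rng("annotation")
    exp_chroms = {c: s for c, s in config.chrom_sizes.items() if not is_spike_chrom(c)}
    spike_chroms = {c: s for c, s in config.chrom_sizes.items() if is_spike_chrom(c)}
    if config.n_genes_exp > 0 and not exp_chroms:
        raise ValueError("no experimental chromosomes in chrom_sizes")
    if config.n_genes_spike > 0 and not spike_chroms:
        raise ValueError("no spike-in chromosomes (prefix %r) in chrom_sizes" % SPIKE_PREFIX)

    rows = []
    for organism, chroms, n_genes, prefix in (
        ("experimental", exp_chroms, config.n_genes_exp, "gene"),
        ("spikein", spike_chroms, config.n_genes_spike, "sp"),
    ):
        if n_genes == 0:
            continue
        names = list(chroms)
        sizes = np.array([chroms[c] for c in names], dtype=float)
        # allocate genes to chromosomes proportionally to length
        alloc = np.floor(sizes / sizes.sum() * n_genes).astype(int)
        for i in range(n_genes - alloc.sum()):
            alloc[i % len(alloc)] += 1
        idx = 0
        for chrom, n_chrom in zip(names, alloc):
            if n_chrom == 0:
                continue
            lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n_chrom)
            needed = int(lengths.sum()) + (n_chrom + 1) * config.min_flank
            size = chroms[chrom]
            if needed > size:
                raise ValueError(
                    f"cannot pack {n_chrom} genes with {config.min_flank} bp flanks on {chrom} ({size} bp)"
                )
            # distribute the slack over the n+1 gaps on top of the minimum flank
            slack = size - needed
            extra = rng.multinomial(slack, np.full(n_chrom + 1, 1.0 / (n_chrom + 1)))
            gaps = extra + config.min_flank
            starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
            strands = rng.choice(["+", "-"], size=n_chrom)
            for j in range(n_chrom):
                rows.append(
                    {
                        "gene_id": f"{prefix}{idx + j:05d}",
                        "chrom": chrom,
                        "start": int(starts[j]),
                        "end": int(starts[j] + lengths[j]),
                        "strand": strands[j],
                        "organism": organism,
                    }
                )
            idx += n_chrom

    if not rows:
        ann = pd.DataFrame(columns=mio.ANNOTATION_COLUMNS)
        return mio.add_tss_tes(ann)

    ann = pd.DataFrame(rows)
    exp_mask = ann["organism"] == "experimental"
    classes = np.array(list(config.class_fractions))
    probs = np.array([config.class_fractions[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    labels = np.full(len(ann), "unannotated", dtype=object)
    labels[exp_mask.values] = rng.choice(classes, size=int(exp_mask.sum()), p=probs)
    ann["gene_class"] = labels
    # TATA boxes are heavily enriched at coactivator-redundant promoters
    p_tata = np.where(ann["gene_class"] == "CR", 0.8, 0.15)
    ann["tata"] = rng.random(len(ann)) < p_tata
    ann.loc[ann["organism"] == "spikein", "tata"] = False
    return mio.add_tss_tes(ann)


def realize_parameters(annotation: pd.DataFrame, config: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Fill in per-gene (q_i, alpha_i, lfc_i) and per-sample depth factors d_j.

    Values supplied on the config are used verbatim; missing ones are drawn
    from the seed. The regulation pattern concentrates down-regulation in CR
    genes (strong effects) and up-regulation in TFIID-dependent genes (mostly
    under two-fold), mirroring the transcriptional signature of losing the
    Mediator tail-core connection. Spike-in genes always have lfc = 0.
    """
    rng = config.rng("params")
    n = len(annotation)
    if config.base_abundance is not None:
        q = np.asarray(config.base_abundance, dtype=float)
        if len(q) != n:
            raise ValueError(f"base_abundance has {len(q)} entries for {n} genes")
    else:
        q = rng.lognormal(mean=np.log(200.0), sigma=0.7, size=n)
    alpha = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (n,)).copy()

    if config.true_log2fc is not None:
        lfc = np.asarray(config.true_log2fc, dtype=float).copy()
        if len(lfc) != n:
            raise ValueError(f"true_log2fc has {len(lfc)} entries for {n} genes")
    else:
        lfc = np.zeros(n)
        cls = annotation["gene_class"].values
        cr = np.flatnonzero(cls == "CR")
        tfiid = np.flatnonzero(cls == "TFIID")
        cr_reg = cr[rng.random(len(cr)) < config.frac_regulated_cr]
        tf_reg = tfiid[rng.random(len(tfiid)) < config.frac_regulated_tfiid]
        lfc[cr_reg] = -rng.uniform(0.5, 2.0, size=len(cr_reg))
        lfc[tf_reg] = rng.uniform(0.3, 1.2, size=len(tf_reg))
    spike = (annotation["organism"] == "spikein").values
    lfc[spike] = 0.0

    m = len(config.sample_ids)
    if config.depth_factors is not None:
        d = np.asarray(config.depth_factors, dtype=float)
        if len(d) != m:
            raise ValueError(f"depth_factors has {len(d)} entries for {m} samples")
    else:
        d = rng.lognormal(mean=0.0, sigma=config.depth_factor_sd, size=m)

    truth = pd.DataFrame(
        {"gene_id": annotation["gene_id"].values, "base_abundance": q, "dispersion": alpha, "true_log2fc": lfc}
    )
    return truth, d


@dataclass
class CountSim:
    counts: pd.DataFrame  # genes x samples, integer
    samples: pd.DataFrame  # sample_id, condition, depth_factor
    gene_truth: pd.DataFrame  # gene_id, base_abundance, dispersion, true_log2fc


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, variance mu + alpha mu^2); Poisson where alpha ~ 0."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / alpha[nb]  # NB "number of successes" parameter
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_counts(annotation: pd.DataFrame, config: SimConfig) -> CountSim:
    """Draw NB counts k_ij with mean d_j * q_i * 2^(lfc_i * x_j).

    x_j is 1 for samples in the second (perturbed) condition. Spike-in gene
    means depend on depth only, so their counts carry the normalization
    signal. One child RNG per sample keeps columns independent.
    """
    truth, d = realize_parameters(annotation, config)
    q = truth["base_abundance"].values
    alpha = truth["dispersion"].values
    lfc = truth["true_log2fc"].values
    bad = ~(np.isfinite(q) & (q > 0))
    if bad.any():
        raise ValueError(f"missing/invalid abundance for genes: {list(truth['gene_id'][bad])}")

    sample_ids = config.sample_ids
    cond = config.sample_conditions
    cols = {}
    for j, (sid, c) in enumerate(zip(sample_ids, cond)):
        x = 1.0 if c == config.conditions[-1] else 0.0
        mu = d[j] * q * np.exp2(lfc * x)
        cols[sid] = _nb_draw(config.rng("counts", j), mu, alpha)
    counts = pd.DataFrame(cols, index=pd.Index(annotation["gene_id"], name="gene_id"))
    samples = pd.DataFrame({"sample_id": sample_ids, "condition": cond, "depth_factor": d})
    return CountSim(counts=counts, samples=samples, gene_truth=truth)


@dataclass
class FragmentSim:
    fragments: pd.DataFrame  # chrom, start, end
    uas_windows: pd.DataFrame  # gene_id, chrom, uas_start, uas_end (ground truth)
    n_clipped: int


def _draw_lengths(rng: np.random.Generator, n: int, mix) -> np.ndarray:
    weights = np.array([m[0] for m in mix], dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(mix), size=n, p=weights)
    lens = np.empty(n)
    for k, (_, mean, sd, lo, hi) in enumerate(mix):
        mask = comp == k
        lens[mask] = np.clip(rng.normal(mean, sd, size=int(mask.sum())), lo, hi)
    return np.maximum(lens.round().astype(np.int64), 1)


def uas_windows(annotation: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Ground-truth UAS window per experimental gene, strand-aware."""
    exp = annotation[annotation["organism"] == "experimental"]
    plus = (exp["strand"] == "+").values
    centre = np.where(plus, exp["tss"].values - config.uas_offset, exp["tss"].values + config.uas_offset)
    half = config.uas_width // 2
    return pd.DataFrame(
        {
            "gene_id": exp["gene_id"].values,
            "chrom": exp["chrom"].values,
            "uas_start": centre - half,
            "uas_end": centre - half + config.uas_width,
        }
    )


def simulate_fragments(annotation: pd.DataFrame, config: SimConfig, factor: str, stream: int = 0) -> FragmentSim:
    """Draw cleavage-fragment spans for one ChEC-style experiment.

    factor:
      ``bound_factor`` — midpoints concentrate in UAS windows upstream of
        TSSs (weight ``uas_signal_weight``) atop uniform background;
      ``free_mnase`` — background only, with ``tes_background_boost``-fold
        elevated cutting in the 500 bp nucleosome-depleted TES regions;
      ``tbp_like`` — short-mode (<=80 bp) fragments footprinting a fixed
        promoter offset (``tbp_offset`` from the TSS, strandwise).

    A ``spikein_fraction`` share of fragments is assigned, per-fragment
    Bernoulli, to the spike-in chromosomes. Fragments running off a
    chromosome end are clipped and counted in ``n_clipped``.
    """
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {FACTORS}, got {factor!r}")
    rng = config.rng("fragments", FACTORS.index(factor), stream)
    n = config.n_fragments
    uas = uas_windows(annotation, config)
    if n == 0:
        return FragmentSim(pd.DataFrame(columns=mio.FRAGMENT_COLUMNS), uas, 0)

    exp_chroms = [c for c in config.chrom_sizes if not is_spike_chrom(c)]
    spike_chroms = [c for c in config.chrom_sizes if is_spike_chrom(c)]
    exp_sizes = np.array([config.chrom_sizes[c] for c in exp_chroms], dtype=float)
    is_spike = rng.random(n) < config.spikein_fraction
    n_spike = int(is_spike.sum())
    n_exp = n - n_spike

    chroms = np.empty(n, dtype=object)
    mids = np.empty(n, dtype=np.int64)

    # spike-in fragments: uniform over spike chromosomes
    if n_spike:
        sp_sizes = np.array([config.chrom_sizes[c] for c in spike_chroms], dtype=float)
        pick = rng.choice(len(spike_chroms), size=n_spike, p=sp_sizes / sp_sizes.sum())
        chroms[is_spike] = np.array(spike_chroms, dtype=object)[pick]
        mids[is_spike] = (rng.random(n_spike) * sp_sizes[pick]).astype(np.int64)

    exp_idx = np.flatnonzero(~is_spike)
    if n_exp:
        if factor == "bound_factor":
            in_uas = rng.random(n_exp) < config.uas_signal_weight
            n_sig = int(in_uas.sum())
            if n_sig and len(uas):
                g = rng.integers(0, len(uas), size=n_sig)
                w_start = uas["uas_start"].values[g]
                w_chrom = uas["chrom"].values[g]
                pos = w_start + rng.integers(0, config.uas_width, size=n_sig)
                sig_rows = exp_idx[in_uas]
                chroms[sig_rows] = w_chrom
                mids[sig_rows] = pos
            else:
                in_uas[:] = False
            bg_rows = exp_idx[~in_uas]
            _uniform_background(rng, bg_rows, chroms, mids, exp_chroms, exp_sizes)
        elif factor == "free_mnase":
            tes = annotation.loc[annotation["organism"] == "experimental", ["chrom", "tes"]]
            tes_starts = np.maximum(tes["tes"].values - 250, 0)
            tes_bp = 500 * len(tes)
            total_bp = exp_sizes.sum()
            boost = config.tes_background_boost
            p_tes = boost * tes_bp / (boost * tes_bp + (total_bp - tes_bp)) if tes_bp else 0.0
            in_tes = rng.random(n_exp) < p_tes
            n_tes = int(in_tes.sum())
            if n_tes:
                g = rng.integers(0, len(tes), size=n_tes)
                rows = exp_idx[in_tes]
                chroms[rows] = tes["chrom"].values[g]
                mids[rows] = tes_starts[g] + rng.integers(0, 500, size=n_tes)
            bg_rows = exp_idx[~in_tes]
            _uniform_background(rng, bg_rows, chroms, mids, exp_chroms, exp_sizes)
        else:  # tbp_like
            exp_genes = annotation[annotation["organism"] == "experimental"]
            plus = (exp_genes["strand"] == "+").values
            site = np.where(plus, exp_genes["tss"].values + config.tbp_offset, exp_genes["tss"].values - config.tbp_offset)
            g = rng.integers(0, len(site), size=n_exp)
            jitter = rng.normal(0.0, config.tbp_jitter_sd, size=n_exp).round().astype(np.int64)
            chroms[exp_idx] = exp_genes["chrom"].values[g]
            mids[exp_idx] = site[g] + jitter

    if factor == "tbp_like":
        short_mix = (config.fraglen_mix[0],)
        lengths = _draw_lengths(rng, n, short_mix)
    else:
        lengths = _draw_lengths(rng, n, config.fraglen_mix)

    starts = mids - lengths // 2
    ends = starts + lengths
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=np.int64)
    clipped = (starts < 0) | (ends > sizes)
    n_clipped = int(clipped.sum())
    if n_clipped:
        logger.info("clipped %d fragments at chromosome bounds", n_clipped)
    starts = np.clip(starts, 0, sizes - 1)
    ends = np.clip(ends, starts + 1, sizes)

    frags = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return FragmentSim(fragments=frags, uas_windows=uas, n_clipped=n_clipped)


def _uniform_background(rng, rows, chroms, mids, chrom_names, sizes):
    if len(rows) == 0:
        return
    pick = rng.choice(len(chrom_names), size=len(rows), p=sizes / sizes.sum())
    chroms[rows] = np.array(chrom_names, dtype=object)[pick]
    mids[rows] = (rng.random(len(rows)) * sizes[pick]).astype(np.int64)


def write_dataset(outdir: str, config: SimConfig) -> dict:
    """Run the full generator and write every output plus ground truth.

    Produces annotation BED6 + label sidecar, counts TSV, samples TSV,
    per-factor fragment BED/BEDPE, and ground-truth TSVs (true lfc, depth
    factors, UAS windows). Returns a dict of written paths.
    """
    mio.ensure_dir(outdir)
    paths = {}
    ann = simulate_annotation(config)
    paths["annotation_bed"] = f"{outdir}/annotation.bed"
    paths["annotation_labels"] = f"{outdir}/annotation_labels.tsv"
    mio.write_annotation(ann, paths["annotation_bed"], paths["annotation_labels"])

    sim = simulate_counts(ann, config)
    paths["counts"] = f"{outdir}/counts.tsv"
    paths["samples"] = f"{outdir}/samples.tsv"
    paths["truth_genes"] = f"{outdir}/truth_genes.tsv"
    paths["truth_samples"] = f"{outdir}/truth_depth_factors.tsv"
    mio.write_counts(sim.counts, paths["counts"])
    mio.write_samples(sim.samples[["sample_id", "condition"]], paths["samples"])
    sim.gene_truth.to_csv(paths["truth_genes"], sep="\t", index=False)
    sim.samples.to_csv(paths["truth_samples"], sep="\t", index=False)

    for factor in FACTORS:
        fsim = simulate_fragments(ann, config, factor)
        paths[f"fragments_{factor}_bed"] = f"{outdir}/fragments_{factor}.bed"
        paths[f"fragments_{factor}_bedpe"] = f"{outdir}/fragments_{factor}.bedpe"
        mio.write_fragments_bed(fsim.fragments, paths[f"fragments_{factor}_bed"])
        mio.write_fragments_bedpe(fsim.fragments, paths[f"fragments_{factor}_bedpe"])
    paths["truth_uas"] = f"{outdir}/truth_uas_windows.tsv"
    uas_windows(ann, config).to_csv(paths["truth_uas"], sep="\t", index=False)
    paths["config"] = f"{outdir}/config_used.yaml"
    config.to_yaml(paths["config"])
    return paths
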