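# Methods

`medtail` implements the quantitative core of a spike-in-anchored study of
transcription-coactivator function in budding yeast: nascent-RNA
differential transcription with size factors estimated on a second-species
spike-in, derivation of concordantly regulated gene sets across two
perturbation strains, and within-sample occupancy scoring of ChEC-seq /
ChIP-seq style signal. A synthetic-data generator with complete ground
truth stands in for the sequencing libraries, so every stage is testable
end to end.

All genomic coordinates are 0-based half-open throughout (BED convention);
TSS = `start` for `+` genes and `end − 1` for `−` genes, TES the opposite
end. A single convention everywhere is what keeps the strand-aware window
arithmetic auditable.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, not raw reads:
no sequencing errors, mappability, duplicates-from-PCR, or RNA stability
effects are modelled. Passing tests therefore demonstrate correctness of
the estimators under the stated stochastic model, not robustness to
alignment artefacts.

**Counts.** Gene counts are negative binomial,
`k_ij ~ NB(mean = d_j · q_i · 2^(lfc_i·x_j), var = μ + α·μ²)`, with
per-sample depth factors `d_j`, per-gene abundances `q_i` (log-normal,
median 200, log-sd 0.7 when not supplied), dispersion `α = 0.05` by default
(typical for yeast biological replicates), and `x_j` indicating the
perturbed condition. Spike-in genes live on chromosomes named with the
`spike_` prefix, always have `lfc = 0`, and respond to depth only — they
are the normalization anchor. The default design is two conditions × 3
replicates. A 0.2 spike-in fragment fraction mirrors a 1:4 spike-in to
experimental mix.

**Regulation pattern.** When true fold changes are not supplied, 60% of
coactivator-redundant (CR) genes are down-regulated with
`lfc ~ −U(0.5, 2)` and 40% of TFIID-dependent genes up-regulated with
`lfc ~ +U(0.3, 1.2)`; class fractions default to 20% CR / 60% TFIID / 20%
unannotated, and TATA-box probability is 0.8 for CR versus 0.15 otherwise.
These choices reproduce the qualitative signature of tail–core separation
(strong CR down-regulation, broad modest TFIID up-regulation) at
magnitudes a nascent-RNA experiment resolves with 3 replicates.

**Fragments.** Cleavage fragments are placed by midpoint. A bound factor
puts 70% of midpoints uniformly inside per-gene UAS windows (100 bp wide,
centred 200 bp upstream of the TSS, strand-aware) and the rest uniformly
on the genome; free MNase is background-only with 3× elevated density in
the 500 bp nucleosome-depleted TES regions; a TBP-like factor footprints a
fixed offset (−60 bp from the TSS, Gaussian jitter sd 8 bp) and draws only
from the short fragment-length mode. Fragment lengths come from a
two-component truncated-normal mixture (35% at 60 ± 10 bp clipped to
[20, 80]; 65% at 150 ± 25 bp clipped to [81, 250]), giving the ≤80 bp
footprint mode the size-filtered profile path selects. Spike-in assignment
is a per-fragment Bernoulli draw, so the requested total is exact and the
spike share binomial.

**Determinism.** One integer seed is expanded through `SeedSequence` into
fixed child streams per (stage, sample), so outputs are byte-identical
across runs and adding a sample never perturbs earlier samples' draws.

## Spike-in normalization

Size factors are the median-of-ratios estimator on the spike-in count
block: `sf_j = median_i k_ij / g_i` over genes with positive geometric
mean `g_i`; genes containing any zero are excluded rather than
pseudocounted, matching the estimator's definition. With an even number of
usable genes the median is the arithmetic midpoint of the two central
ratios. Factors are reported raw (not rescaled to unit geometric mean) for
transparency; downstream results are invariant to the common constant
because the DE routines rescale internally (below).

ChEC spike-in scale factors are `scale_j ∝ 1 / n_spike_j` with the
constant fixed by a mean-1 convention across samples — the convention is
ours, since only relative scales matter for track comparison.

## Differential transcription

A deliberately transparent two-group NB Wald test; no dispersion trend or
fold-change shrinkage, no independent filtering, no outlier refitting. Its
guarantees are established by simulation (FDR control on all-null data,
recovery of ±1 log2 effects) rather than by numerical equivalence to any
reference package.

- Size factors are given (from the spike-in), never re-estimated. They are
  internally rescaled to unit geometric mean, which makes every reported
  quantity exactly invariant to a common rescaling of the factors.
- Dispersion: per-gene method of moments on normalized counts within each
  condition, `α = (s² − m)/m²` floored at 1e-8 and averaged across
  conditions.
- Test: group means of normalized counts plus a 0.5 pseudocount (prevents
  infinite fold changes at zero counts); `log2fc = log2(μ_B/μ_A)`;
  `se² = (1/ln2)²·(v_A/(n_A μ_A²) + v_B/(n_B μ_B²))` with `v` the
  within-group variance floored at the NB moment value
  `μ·mean(1/sf) + α·μ²` (the `mean(1/sf)` term keeps the floor
  scale-equivariant); two-sided normal p; BH across tested genes. Genes
  with all-zero counts are flagged `low_count` and excluded from the BH
  denominator.
- Robustness floor: per-gene moment dispersions at 3 replicates are noisy
  and collapse to the floor exactly when the sample variance is also small
  by chance — the same lucky genes would pass both variance guards and
  inflate the Wald statistic. The test therefore floors each gene's
  dispersion at the dataset median of the per-gene estimates (applied only
  when ≥20 genes are available). This is a variance floor, not
  empirical-Bayes shrinkage toward a mean-dispersion trend; for datasets
  with genuinely heterogeneous dispersions it is mildly conservative for
  the quietest genes. With it, all-null simulations at dispersions
  0.05–0.2 show ~0.005% of genes at padj < 0.05 (target ≤1%) while
  detected ±1 effects are recovered with |bias| < 0.05 and 100% sign
  accuracy.

## Gene sets

Significant sets are `padj < 0.05` split by fold-change sign. Two
contrasts combine as: union of genes significant in either, retaining
genes whose fold changes share a sign in both — direction, not dual
significance, is the filter. Genes with a zero/undefined fold change count
as discordant; genes missing from one table form their own category; the
four categories always sum to the union (asserted property). Overlap
fractions, class composition (denominator excludes unannotated genes), and
the fraction changed by less than 2-fold (`2^|lfc| < 2`, strict) are
reported as percentages rounded half-up to one decimal.

## Coverage and occupancy scoring

Tracks are full-fragment-span pileups (each fragment adds 1 across its
span), binned at 10 bp by per-bp mean, normalized per-million/CPM (total
fragment count maps to 1e6), by a supplied spike scale, or left raw.
Cut-end pileup is available as an alternative via midpoint-free spans but
full-span is the default to match how browser tracks are conventionally
built. Window sums weight partial bins by overlap fraction and agree with
a per-bp recount to 1e-9.

The per-gene enrichment score is `log2((upstream + pc)/(TESR + pc))` with
upstream `[TSS−500, TSS)` strand-aware, TESR `[TES−250, TES+250)`, and a
pseudocount of 1 normalized unit (default) — zero-TESR genes otherwise
produce infinities; both the pseudocount and zero-handling are parameters
because no single convention is canonical. Windows clipped at chromosome
edges are flagged rather than dropped.

Group contrasts use the two-sided Wilcoxon rank-sum test — exact null
distribution when both groups have ≤8 untied values, tie-corrected normal
approximation otherwise — with Holm correction across pairs when more
than two groups are compared.

The footprint profile keeps fragments ≤80 bp (dropping exact
(chrom, start, end) duplicates, since at footprint scale identical spans
are overwhelmingly duplicates), CPM-normalizes, extracts the 2 kb window
centred on each TSS (oriented upstream-left), and averages per 10 bp bin
across the gene group. The window is anchored on the TSS's bin, so peak
positions carry a ≤bin-size quantization error. Averaging commutes with
gene-group partitioning (asserted property).

## Pipeline

`run_pipeline` executes simulate → normalize → detest → genesets →
chec-score → tbp-profile over plain files in one output directory, writing
a manifest with the config hash, seed, and SHA-256 digest of every input
and output; deterministic stages reproduce identical digests under the
same seed. The simulate stage produces two datasets sharing one truth
pattern — a full-effect contrast and a 0.6-attenuated one — mirroring a
deletion strain versus an acute-depletion strain, which is what gives the
genesets stage a meaningful concordance structure.

## Problem sizes

Test and acceptance runs use 2,000-gene count simulations (3 vs 3), 50
spike-in genes, 20-seed repetition for calibration estimates, and
30,000–40,000-fragment ChEC libraries over 150–200 genes. These sizes give
Monte-Carlo error comfortably below every asserted tolerance while keeping
a full run in seconds.

## Known limitations

- The DE model is two-group only: no multi-factor designs, interactions,
  or continuous covariates.
- Dispersion estimation is method-of-moments; for very low counts
  (μ < ~10) the Wald test loses power relative to likelihood-based
  approaches, though calibration is preserved by the variance floors.
- The generator does not model alignment, duplicates, mappability, GC
  bias, or RNA stability; conclusions about those failure modes cannot be
  drawn from these simulations.
- Enrichment scores at genes shorter than the TESR window mix gene-body
  and TES signal; they are flagged only when windows leave the
  chromosome.
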