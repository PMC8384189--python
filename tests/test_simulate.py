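"""Generator correctness: packing, determinism, NB moments, fragment placement."""

import numpy as np
import pandas as pd
import pytest

import medtail.io as mio
from medtail import SimConfig, simulate_annotation, simulate_counts, simulate_fragments, write_dataset
from medtail.simulate import _nb_draw, uas_windows


class TestAnnotation:
    def test_empty_annotation_is_valid_and_writable(self, tmp_path):
        cfg = SimConfig(seed=1, n_genes_exp=0, n_genes_spike=0)
        ann = simulate_annotation(cfg)
        assert len(ann) == 0
        mio.write_annotation(ann, str(tmp_path / "a.bed"), str(tmp_path / "l.tsv"))
        back = mio.read_annotation(str(tmp_path / "a.bed"), str(tmp_path / "l.tsv"))
        assert len(back) == 0

    def test_fixed_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=7, n_genes_exp=30, n_genes_spike=10, n_fragments=500)
        p1 = write_dataset(str(tmp_path / "r1"), cfg)
        p2 = write_dataset(str(tmp_path / "r2"), cfg)
        for key in ("annotation_bed", "counts", "fragments_bound_factor_bedpe", "truth_genes"):
            b1 = open(p1[key], "rb").read()
            b2 = open(p2[key], "rb").read()
            assert b1 == b2, f"{key} differs between identical-seed runs"

    def test_genes_do_not_overlap_brute_force(self):
        cfg = SimConfig(seed=5, n_genes_exp=50, n_genes_spike=0, chrom_sizes={"chrI": 1_000_000})
        ann = simulate_annotation(cfg)
        assert len(ann) == 50
        # brute-force pairwise interval sweep
        for chrom, sub in ann.groupby("chrom"):
            ivals = sorted(zip(sub["start"], sub["end"]))
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                assert e1 <= s2, f"overlap on {chrom}"
        assert (ann["start"] >= 0).all()
        assert (ann["end"] <= 1_000_000).all()

    def test_requested_counts_and_organism_split(self, annotation, small_config):
        assert (annotation["organism"] == "experimental").sum() == small_config.n_genes_exp
        assert (annotation["organism"] == "spikein").sum() == small_config.n_genes_spike
        assert annotation["gene_id"].is_unique
        spike = annotation[annotation["organism"] == "spikein"]
        assert spike["chrom"].str.startswith("spike_").all()

    def test_infeasible_packing_names_chromosome(self):
        cfg = SimConfig(seed=1, n_genes_exp=500, n_genes_spike=0, chrom_sizes={"chrTiny": 50_000})
        with pytest.raises(ValueError, match="chrTiny"):
            simulate_annotation(cfg)

    def test_tss_tes_follow_strand(self, annotation):
        plus = annotation[annotation["strand"] == "+"]
        minus = annotation[annotation["strand"] == "-"]
        assert (plus["tss"] == plus["start"]).all()
        assert (minus["tss"] == minus["end"] - 1).all()
        assert (plus["tes"] == plus["end"] - 1).all()
        assert (minus["tes"] == minus["start"]).all()


class TestCounts:
    def test_poisson_limit_mean(self, rng):
        draws = _nb_draw(rng, np.full(10_000, 100.0), np.zeros(10_000))
        se = np.sqrt(100.0 / 10_000)
        assert abs(draws.mean() - 100.0) < 3 * se

    def test_nb_variance_matches_moment_formula(self, rng):
        # var = mu + alpha mu^2 = 100 + 0.1 * 1e4 = 1100
        draws = _nb_draw(rng, np.full(10_000, 100.0), np.full(10_000, 0.1))
        var = draws.var(ddof=1)
        # MC tolerance: sd of the sample variance ~ var * sqrt(2/n + kurtosis term)
        assert abs(draws.mean() - 100.0) < 3 * np.sqrt(1100 / 10_000)
        assert 950 < var < 1270

    def test_spikein_counts_do_not_respond_to_condition(self):
        cfg = SimConfig(
            seed=9,
            n_genes_exp=5,
            n_genes_spike=40,
            replicates_per_condition=30,
            depth_factors=np.ones(60),
        )
        ann = simulate_annotation(cfg)
        sim = simulate_counts(ann, cfg)
        spike_ids = ann.loc[ann["organism"] == "spikein", "gene_id"]
        cond = pd.Series(sim.samples["condition"].values, index=sim.samples["sample_id"].values)
        spike = sim.counts.loc[spike_ids]
        m_a = spike.loc[:, cond == "control"].mean(axis=1)
        m_b = spike.loc[:, cond == "depleted"].mean(axis=1)
        # equal depth, lfc = 0 by invariant: group means agree within sampling error
        pooled_se = np.sqrt((spike.var(axis=1, ddof=1) * 2 / 30).astype(float))
        assert (np.abs(m_a - m_b) < 4 * pooled_se + 1).all()
        assert (sim.gene_truth.set_index("gene_id").loc[spike_ids, "true_log2fc"] == 0).all()

    def test_bad_abundance_raises_with_gene_names(self, annotation, small_config):
        from dataclasses import replace

        q = np.full(len(annotation), 100.0)
        q[3] = np.nan
        cfg = replace(small_config, base_abundance=q)
        with pytest.raises(ValueError, match=annotation["gene_id"].iloc[3]):
            simulate_counts(annotation, cfg)


class TestFragments:
    def test_spikein_fraction_zero_means_no_spike_fragments(self, annotation, small_config):
        from dataclasses import replace

        cfg = replace(small_config, spikein_fraction=0.0)
        sim = simulate_fragments(annotation, cfg, "bound_factor")
        assert not sim.fragments["chrom"].str.startswith("spike_").any()

    def test_pure_signal_midpoints_all_inside_uas_windows(self, annotation, small_config):
        from dataclasses import replace

        cfg = replace(small_config, uas_signal_weight=1.0, spikein_fraction=0.0, n_fragments=2000)
        sim = simulate_fragments(annotation, cfg, "bound_factor")
        uas = uas_windows(annotation, cfg)
        mids = (sim.fragments["start"] + sim.fragments["end"]) // 2
        # brute-force membership scan against the ground-truth windows
        windows = {}
        for w in uas.itertuples(index=False):
            windows.setdefault(w.chrom, []).append((w.uas_start, w.uas_end))
        n_unclipped = 0
        inside = 0
        for chrom, mid, s, e in zip(sim.fragments["chrom"], mids, sim.fragments["start"], sim.fragments["end"]):
            if any(a <= mid < b for a, b in windows.get(chrom, [])):
                inside += 1
        # clipping at chromosome edges can move a midpoint; tolerate those only
        assert inside >= len(sim.fragments) - sim.n_clipped

    def test_total_count_exact_and_spike_share_binomial(self, annotation, small_config):
        sim = simulate_fragments(annotation, small_config, "free_mnase")
        n = small_config.n_fragments
        assert len(sim.fragments) == n
        share = sim.fragments["chrom"].str.startswith("spike_").mean()
        p = small_config.spikein_fraction
        assert abs(share - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_tbp_like_fragments_are_all_short(self, annotation, small_config):
        sim = simulate_fragments(annotation, small_config, "tbp_like")
        lengths = sim.fragments["end"] - sim.fragments["start"]
        assert (lengths <= 80).all()

    def test_free_mnase_background_is_boosted_at_tes(self, annotation, small_config):
        from dataclasses import replace

        cfg = replace(small_config, spikein_fraction=0.0, n_fragments=30_000, tes_background_boost=5.0)
        sim = simulate_fragments(annotation, cfg, "free_mnase")
        mids = ((sim.fragments["start"] + sim.fragments["end"]) // 2).to_numpy()
        exp = annotation[annotation["organism"] == "experimental"]
        in_tes = np.zeros(len(mids), dtype=bool)
        for g in exp.itertuples(index=False):
            in_tes |= (sim.fragments["chrom"].to_numpy() == g.chrom) & (mids >= g.tes - 250) & (mids < g.tes + 250)
        tes_bp = 500 * len(exp)
        genome_bp = sum(s for c, s in cfg.chrom_sizes.items() if not c.startswith("spike_"))
        dens_ratio = (in_tes.mean() / tes_bp) / ((1 - in_tes.mean()) / (genome_bp - tes_bp))
        assert dens_ratio > 2.5  # should approach the configured 5x boost

    def test_unknown_factor_rejected(self, annotation, small_config):
        with pytest.raises(ValueError, match="factor"):
            simulate_fragments(annotation, small_config, "nonsense")


def test_ground_truth_round_trips_through_readers(tmp_path):
    cfg = SimConfig(seed=3, n_genes_exp=20, n_genes_spike=8, n_fragments=400)
    paths = write_dataset(str(tmp_path / "d"), cfg)
    ann = mio.read_annotation(paths["annotation_bed"], paths["annotation_labels"])
    counts = mio.read_counts(paths["counts"])
    truth = pd.read_csv(paths["truth_genes"], sep="\t")
    frags_bed = mio.read_fragments_bed(paths["fragments_bound_factor_bed"])
    frags_pe = mio.read_fragments_bedpe(paths["fragments_bound_factor_bedpe"])
    assert list(counts.index) == list(ann["gene_id"]) == list(truth["gene_id"])
    assert len(frags_bed) == cfg.n_fragments
    # BEDPE mate pairs span exactly the fragment intervals of the BED
    pd.testing.assert_frame_equal(frags_bed, frags_pe)
    cfg2 = SimConfig.from_yaml(paths["config"])
    assert cfg2.seed == cfg.seed and cfg2.n_genes_exp == cfg.n_genes_exp
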