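"""Coverage tracks, window sums, enrichment ratios, group tests, TSS profiles."""

import numpy as np
import pandas as pd
import pytest

import medtail.io as mio
from medtail import (
    SignalTrack,
    SimConfig,
    compare_groups,
    compare_groups_pairwise,
    fragment_coverage,
    simulate_annotation,
    simulate_fragments,
    size_filtered_profile,
    upstream_tesr_scores,
    window_signal,
)

SIZES = {"chrT": 10_000}


def frag(chrom, start, end):
    return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})


def uniform_track(value=2.0, size=10_000, bin_size=10):
    n = size // bin_size
    return SignalTrack(values={"chrT": np.full(n, float(value))}, bin_size=bin_size, chrom_sizes={"chrT": size})


class TestFragmentCoverage:
    def test_single_fragment_per_million_weight(self):
        track = fragment_coverage(frag("chrT", 1000, 1100), SIZES, bin_size=10, normalization="per-million")
        vals = track.values["chrT"]
        covered = vals[100:110]
        np.testing.assert_allclose(covered, 1e6)  # one fragment carries the full 1e6
        assert vals[:100].sum() == 0 and vals[110:].sum() == 0

    def test_empty_fragment_set_warns_and_returns_zero(self):
        empty = pd.DataFrame({"chrom": [], "start": [], "end": []})
        with pytest.warns(UserWarning, match="empty"):
            track = fragment_coverage(empty.astype({"chrom": str}), SIZES)
        assert track.total() == 0.0

    def test_duplication_invariant_under_per_million(self):
        frags = pd.DataFrame({"chrom": ["chrT"] * 3, "start": [100, 500, 900], "end": [200, 650, 1000]})
        doubled = pd.concat([frags, frags], ignore_index=True)
        t1 = fragment_coverage(frags, SIZES)
        t2 = fragment_coverage(doubled, SIZES)
        np.testing.assert_allclose(t1.values["chrT"], t2.values["chrT"])

    def test_out_of_bounds_fragment_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            track = fragment_coverage(frag("chrT", 9950, 10_100), SIZES, normalization="none")
        assert track.values["chrT"][995:].sum() == pytest.approx(5.0)  # 50 bp kept

    def test_spike_scaled_requires_scale(self):
        with pytest.raises(ValueError, match="scale"):
            fragment_coverage(frag("chrT", 0, 10), SIZES, normalization="spike-scaled")


class TestWindowSignal:
    def test_zero_track(self):
        track = uniform_track(0.0)
        assert window_signal(track, "chrT", 100, 600) == 0.0

    def test_uniform_track_full_bins(self):
        track = uniform_track(3.0)
        assert window_signal(track, "chrT", 200, 700) == pytest.approx(3.0 * 50)

    def test_unknown_chrom_raises(self):
        with pytest.raises(KeyError):
            window_signal(uniform_track(), "chrX", 0, 10)

    def test_matches_per_bp_brute_force_on_random_windows(self, rng):
        vals = rng.random(1000)
        track = SignalTrack(values={"chrT": vals}, bin_size=10, chrom_sizes={"chrT": 10_000})
        for _ in range(50):
            a, b = sorted(rng.integers(0, 10_000, size=2))
            if a == b:
                b += 1
            # brute force: every bp contributes its bin's value / bin_size
            expected = sum(vals[p // 10] / 10 for p in range(a, b))
            assert window_signal(track, "chrT", a, b) == pytest.approx(expected, abs=1e-9)


class TestUpstreamTesrScores:
    def _gene(self, strand="+", start=4000, end=6000):
        ann = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chrT"], "start": [start], "end": [end], "strand": [strand]}
        )
        return mio.add_tss_tes(ann)

    def test_uniform_signal_gives_zero_ratio(self):
        scores = upstream_tesr_scores(uniform_track(2.0), self._gene())
        assert scores.loc["g1", "log2_ratio"] == 0.0
        assert not scores.loc["g1", "clipped"]

    def test_constructed_counts_give_ratio_two(self):
        # 400 fragment-units upstream, 100 in the TES region, negligible pseudocount
        gene = self._gene()  # + strand: upstream [3500,4000), TESR [5749-250.. wait uses tes=5999
        frags = pd.concat(
            [frag("chrT", 3600, 3700)] * 400 + [frag("chrT", 5900, 6000)] * 100, ignore_index=True
        )
        track = fragment_coverage(frags, SIZES, normalization="none")
        scores = upstream_tesr_scores(track, gene, pseudocount=1e-9)
        assert scores.loc["g1", "log2_ratio"] == pytest.approx(2.0, abs=1e-6)

    def test_minus_strand_mirror_symmetry(self):
        size = 10_000
        plus = self._gene("+", 4000, 6000)
        minus = self._gene("-", size - 6000, size - 4000)
        f_plus = frag("chrT", 3600, 3700)
        f_minus = frag("chrT", size - 3700, size - 3600)
        t_plus = fragment_coverage(f_plus, SIZES, normalization="none")
        t_minus = fragment_coverage(f_minus, SIZES, normalization="none")
        s_plus = upstream_tesr_scores(t_plus, plus)
        s_minus = upstream_tesr_scores(t_minus, minus)
        assert s_plus.loc["g1", "upstream_signal"] == pytest.approx(s_minus.loc["g1", "upstream_signal"])
        assert s_plus.loc["g1", "log2_ratio"] == pytest.approx(s_minus.loc["g1", "log2_ratio"])

    def test_window_clipped_at_chrom_edge_is_flagged(self):
        scores = upstream_tesr_scores(uniform_track(1.0), self._gene(start=200, end=900))
        assert bool(scores.loc["g1", "clipped"])

    def test_rescaling_invariance_with_zero_pseudocount(self):
        frags = pd.concat([frag("chrT", 3600, 3700)] * 5 + [frag("chrT", 5900, 6000)] * 3, ignore_index=True)
        gene = self._gene()
        a = upstream_tesr_scores(fragment_coverage(frags, SIZES, normalization="per-million"), gene, pseudocount=0.0)
        b = upstream_tesr_scores(fragment_coverage(frags, SIZES, normalization="none"), gene, pseudocount=0.0)
        assert a.loc["g1", "log2_ratio"] == pytest.approx(b.loc["g1", "log2_ratio"])


class TestCompareGroups:
    def test_identical_groups_near_one(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p_value"] >= 0.99

    def test_fully_separated_three_vs_three_exact(self):
        # all 3 of B above all of A: U = 9, exact two-sided p = 2 * 1/C(6,3) = 0.1
        res = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res["method"] == "exact"
        assert res["p_value"] == pytest.approx(0.1)

    def test_shift_invariance(self):
        a = np.array([0.3, 1.2, 0.9, 2.0])
        b = np.array([1.1, 1.9, 2.5, 0.7])
        p1 = compare_groups(a, b)["p_value"]
        p2 = compare_groups(a + 100, b + 100)["p_value"]
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0, 2.0])

    def test_pairwise_holm_structure(self, rng):
        groups = {k: rng.normal(loc, 1.0, size=20) for k, loc in (("a", 0.0), ("b", 0.1), ("c", 3.0))}
        tab = compare_groups_pairwise(groups)
        assert len(tab) == 3
        assert (tab["p_holm"] >= tab["p_value"] - 1e-15).all()
        strong = tab[(tab["group_a"] == "a") & (tab["group_b"] == "c")]
        assert strong["p_holm"].iloc[0] < 0.01


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(seed=17, n_genes_exp=120, n_genes_spike=10, n_fragments=30_000)
    ann = simulate_annotation(cfg)
    frags = simulate_fragments(ann, cfg, "tbp_like").fragments
    return cfg, ann[ann["organism"] == "experimental"], frags


class TestSizeFilteredProfile:

    def test_all_long_fragments_give_zero_profile(self, sim):
        cfg, ann, _ = sim
        frags = pd.DataFrame({"chrom": ["chrI"] * 5, "start": np.arange(5) * 1000, "end": np.arange(5) * 1000 + 120})
        with pytest.warns(UserWarning, match="size filter"):
            prof = size_filtered_profile(frags, ann, cfg.chrom_sizes)
        assert prof.values.sum() == 0.0

    def test_peak_recovered_at_simulated_offset(self, sim):
        cfg, ann, frags = sim
        prof = size_filtered_profile(frags, ann, cfg.chrom_sizes)
        peak = prof.positions[np.argmax(prof.values)]
        assert abs(peak - cfg.tbp_offset) <= 20

    def test_duplicate_handling_noop_on_unique_input(self, sim):
        cfg, ann, frags = sim
        unique = frags.drop_duplicates(subset=["chrom", "start", "end"])
        p_on = size_filtered_profile(unique, ann, cfg.chrom_sizes, ignore_duplicates=True)
        p_off = size_filtered_profile(unique, ann, cfg.chrom_sizes, ignore_duplicates=False)
        np.testing.assert_allclose(p_on.values, p_off.values)

    def test_group_partition_commutes_with_averaging(self, sim):
        cfg, ann, frags = sim
        full = size_filtered_profile(frags, ann, cfg.chrom_sizes)
        ids = list(ann["gene_id"])
        g1, g2 = set(ids[:40]), set(ids[40:])
        p1 = size_filtered_profile(frags, ann, cfg.chrom_sizes, genes=g1)
        p2 = size_filtered_profile(frags, ann, cfg.chrom_sizes, genes=g2)
        weighted = (p1.values * len(g1) + p2.values * len(g2)) / len(ids)
        np.testing.assert_allclose(weighted, full.values, rtol=1e-9)


def test_bound_factor_scores_exceed_free_mnase_by_over_one(annotation, small_config):
    """Mean enrichment gap between a UAS-bound factor and free MNase."""
    exp = annotation[annotation["organism"] == "experimental"]
    means = {}
    for factor in ("bound_factor", "free_mnase"):
        frags = simulate_fragments(annotation, small_config, factor).fragments
        track = fragment_coverage(frags, small_config.chrom_sizes)
        means[factor] = upstream_tesr_scores(track, exp)["log2_ratio"].mean()
    assert means["bound_factor"] - means["free_mnase"] > 1.0
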