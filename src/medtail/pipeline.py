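"""End-to-end orchestration: simulate -> normalize -> detest -> genesets -> chec-score/tbp-profile.

Plain files plus a manifest instead of a workflow engine: every stage reads
and writes TSV/BED under one output directory, and the manifest records the
config hash, seed, and SHA-256 digest of each input and output so a run is
auditable and exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace

import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .simulate import SimConfig, SPIKE_PREFIX, write_dataset
from .normalize import size_factors_median_of_ratios, chec_scale_factors
from .diffexpr import wald_test_two_group
from .genesets import concordant_union, venn_overlap, class_fractions, magnitude_fraction, significant_sets
from .coverage import fragment_coverage, upstream_tesr_scores, compare_groups, size_filtered_profile

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "detest", "genesets", "chec_score", "tbp_profile")


class PipelineConfigError(ValueError):
    pass


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config must be a mapping")
    unknown = set(cfg) - {"seed", "outdir", "stages", "simulate", "detest", "genesets", "chec_score", "tbp_profile"}
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def run_pipeline(config: dict | str, outdir: str | None = None, seed: int | None = None) -> dict:
    """Execute the requested stages in dependency order and write a manifest.

    ``config`` is a dict or a YAML path. Each stage's outputs land under
    ``outdir``; the returned manifest maps stage -> {inputs, outputs,
    seconds} with file digests. Raises ``PipelineConfigError`` naming any
    missing key a requested stage needs.
    """
    cfg = load_config(config) if isinstance(config, str) else dict(config)
    outdir = outdir or cfg.get("outdir")
    if not outdir:
        raise PipelineConfigError("missing required key: outdir")
    mio.ensure_dir(outdir)
    seed = seed if seed is not None else cfg.get("seed", 0)
    stages = cfg.get("stages", list(STAGES))
    bad = set(stages) - set(STAGES)
    if bad:
        raise PipelineConfigError(f"unknown stages: {sorted(bad)}")

    manifest = {
        "tool_version": __version__,
        "seed": int(seed),
        "config_sha256": hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "stages": {},
    }
    paths: dict = {}

    def record(stage, inputs, outputs, t0):
        manifest["stages"][stage] = {
            "inputs": {k: _sha256(v) for k, v in inputs.items()},
            "outputs": {k: _sha256(v) for k, v in outputs.items()},
            "seconds": round(time.monotonic() - t0, 3),
        }
        logger.info("stage %s done in %.2fs", stage, manifest["stages"][stage]["seconds"])

    if "simulate" in stages:
        t0 = time.monotonic()
        sim_cfg = SimConfig(**{"seed": int(seed), **cfg.get("simulate", {})})
        # two perturbation datasets sharing one truth pattern: a strong
        # (deletion-like) contrast and an attenuated (acute-depletion-like) one
        paths["run1"] = write_dataset(f"{outdir}/strain1", sim_cfg)
        truth = pd.read_csv(paths["run1"]["truth_genes"], sep="\t")
        atten = cfg.get("simulate", {}).get("attenuation", 0.6)
        cfg2 = replace(
            sim_cfg,
            seed=int(seed) + 1,
            true_log2fc=truth["true_log2fc"].to_numpy() * atten,
            base_abundance=truth["base_abundance"].to_numpy(),
        )
        paths["run2"] = write_dataset(f"{outdir}/strain2", cfg2)
        record("simulate", {}, {f"{k}_{r}": v for r in ("run1", "run2") for k, v in paths[r].items()}, t0)

    for run in ("run1", "run2"):
        if run not in paths:
            continue
        rp = paths[run]
        if "normalize" in stages:
            t0 = time.monotonic()
            counts = mio.read_counts(rp["counts"])
            labels = pd.read_csv(rp["annotation_labels"], sep="\t")
            spike_ids = labels.loc[labels["organism"] == "spikein", "gene_id"]
            sf = size_factors_median_of_ratios(counts.loc[spike_ids])
            rp["size_factors"] = rp["counts"].replace("counts.tsv", "size_factors.tsv")
            mio.write_size_factors(sf.factors, sf.n_genes_used, rp["size_factors"])
            record(f"normalize_{run}", {"counts": rp["counts"]}, {"size_factors": rp["size_factors"]}, t0)
        if "detest" in stages:
            if "size_factors" not in rp:
                raise PipelineConfigError(f"detest stage requires normalize outputs for {run}")
            t0 = time.monotonic()
            counts = mio.read_counts(rp["counts"])
            samples = mio.read_samples(rp["samples"])
            sf = mio.read_size_factors(rp["size_factors"])
            cond = pd.Series(samples["condition"].values, index=samples["sample_id"].values)
            contrast = tuple(cfg.get("detest", {}).get("contrast", ("control", "depleted")))
            labels = pd.read_csv(rp["annotation_labels"], sep="\t")
            exp_ids = labels.loc[labels["organism"] == "experimental", "gene_id"]
            de = wald_test_two_group(counts.loc[exp_ids], sf, cond, contrast)
            rp["de"] = rp["counts"].replace("counts.tsv", "de_results.tsv")
            mio.write_de_table(de, rp["de"])
            record(f"detest_{run}", {"counts": rp["counts"], "size_factors": rp["size_factors"]}, {"de": rp["de"]}, t0)

    if "genesets" in stages:
        for run in ("run1", "run2"):
            if run not in paths or "de" not in paths[run]:
                raise PipelineConfigError("genesets stage requires detest outputs for both runs")
        t0 = time.monotonic()
        de1 = mio.read_de_table(paths["run1"]["de"])
        de2 = mio.read_de_table(paths["run2"]["de"])
        alpha = cfg.get("genesets", {}).get("alpha", 0.05)
        sets = concordant_union(de1, de2, alpha=alpha)
        labels = pd.read_csv(paths["run1"]["annotation_labels"], sep="\t").set_index("gene_id")["gene_class"]
        up1, down1 = significant_sets(de1, alpha)
        up2, down2 = significant_sets(de2, alpha)
        summary = sets.summary()
        extra = pd.DataFrame(
            [
                {"category": "venn_up_intersection", "n_genes": venn_overlap(up2, up1)["n_intersection"]},
                {"category": "venn_down_intersection", "n_genes": venn_overlap(down2, down1)["n_intersection"]},
            ]
        )
        summary = pd.concat([summary, extra], ignore_index=True)
        out = {
            "summary": f"{outdir}/geneset_summary.tsv",
            "down": f"{outdir}/concordant_down.txt",
            "up": f"{outdir}/concordant_up.txt",
            "class_fractions": f"{outdir}/class_fractions.tsv",
        }
        summary.to_csv(out["summary"], sep="\t", index=False)
        for key, s in (("down", sets.concordant_down), ("up", sets.concordant_up)):
            with open(out[key], "w") as fh:
                fh.writelines(f"{g}\n" for g in sorted(s))
        frac_down = class_fractions(sets.concordant_down, labels).assign(gene_set="down")
        frac_up = class_fractions(sets.concordant_up, labels).assign(gene_set="up")
        mag = magnitude_fraction(sets.concordant_up, de1["log2fc"]) if sets.concordant_up else {}
        fr = pd.concat([frac_down, frac_up], ignore_index=True)
        fr.to_csv(out["class_fractions"], sep="\t", index=False)
        with open(f"{outdir}/magnitude_fraction.json", "w") as fh:
            json.dump(mag, fh, indent=1)
        out["magnitude"] = f"{outdir}/magnitude_fraction.json"
        record("genesets", {"de1": paths["run1"]["de"], "de2": paths["run2"]["de"]}, out, t0)
        paths["genesets"] = out

    if "chec_score" in stages:
        if "run1" not in paths:
            raise PipelineConfigError("chec_score stage requires simulate outputs")
        t0 = time.monotonic()
        rp = paths["run1"]
        ann = mio.read_annotation(rp["annotation_bed"], rp["annotation_labels"])
        sim_cfg = SimConfig.from_yaml(rp["config"])
        exp_ann = ann[ann["organism"] == "experimental"]
        cs = cfg.get("chec_score", {})
        out = {"scores": f"{outdir}/chec_scores.tsv", "comparison": f"{outdir}/chec_comparison.tsv"}
        score_frames, spike_counts = [], {}
        for factor in ("bound_factor", "free_mnase"):
            frags = mio.read_fragments_bed(rp[f"fragments_{factor}_bed"])
            spike_counts[factor] = int(frags["chrom"].str.startswith(SPIKE_PREFIX).sum())
            track = fragment_coverage(
                frags, sim_cfg.chrom_sizes, bin_size=cs.get("bin_size", 10), normalization=cs.get("normalization", "per-million")
            )
            scores = upstream_tesr_scores(
                track, exp_ann, upstream_len=cs.get("upstream_len", 500), tesr_len=cs.get("tesr_len", 500)
            )
            score_frames.append(scores.assign(factor=factor))
        scores_all = pd.concat(score_frames)
        scores_all.to_csv(out["scores"], sep="\t")
        comp = compare_groups(
            score_frames[0]["log2_ratio"].to_numpy(), score_frames[1]["log2_ratio"].to_numpy()
        )
        scales = chec_scale_factors(pd.Series(spike_counts))
        comp["spike_scale_bound_factor"] = float(scales["bound_factor"])
        comp["spike_scale_free_mnase"] = float(scales["free_mnase"])
        pd.DataFrame([comp]).to_csv(out["comparison"], sep="\t", index=False)
        record("chec_score", {"fragments": rp["fragments_bound_factor_bed"]}, out, t0)
        paths["chec_score"] = out

    if "tbp_profile" in stages:
        if "run1" not in paths:
            raise PipelineConfigError("tbp_profile stage requires simulate outputs")
        t0 = time.monotonic()
        rp = paths["run1"]
        ann = mio.read_annotation(rp["annotation_bed"], rp["annotation_labels"])
        sim_cfg = SimConfig.from_yaml(rp["config"])
        tp = cfg.get("tbp_profile", {})
        frags = mio.read_fragments_bed(rp["fragments_tbp_like_bed"])
        prof = size_filtered_profile(
            frags,
            ann[ann["organism"] == "experimental"],
            sim_cfg.chrom_sizes,
            max_len=tp.get("max_fragment_length", 80),
            flank=tp.get("flank", 1000),
            bin_size=tp.get("bin_size", 10),
        )
        out = {"profile": f"{outdir}/tbp_profile.tsv"}
        pd.DataFrame({"position": prof.positions, "mean_cpm": prof.values}).to_csv(out["profile"], sep="\t", index=False)
        record("tbp_profile", {"fragments": rp["fragments_tbp_like_bed"]}, out, t0)
        paths["tbp_profile"] = out

    manifest_path = f"{outdir}/manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["manifest_path"] = manifest_path
    return manifest
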