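"""End-to-end orchestration: simulate -> peaks -> targets -> wTO -> CoDiNA
-> SOM -> atlas -> miRNA, with a JSON run manifest.

Every stage default equals the published analysis value (background 10
reads, 20%/5% splits, BH alpha 0.05, 1000 bootstraps, probability cut 0.10,
RPKM floor 5, |r| > 0.9, distance cut 0.5, chi-square alpha 0.05, 1000 top
genes, 200 counts).  One master seed deterministically derives every stage
seed, so a rerun with the same config is identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ripnet import atlas as atlas_mod
from ripnet import codina, mirna, peaks, som, synthio, targets, wto
from ripnet.containers import ExpressionMatrix, read_bedgraph, sites_to_bed
from ripnet.peaks import SiteParams
from ripnet.wto import WTOParams

STAGES = ("simulate", "peaks", "targets", "wto", "codina", "som", "atlas", "mirna")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results"
    data_dir: str | None = None          # pre-existing inputs; None -> simulate
    stages: tuple[str, ...] = STAGES
    synth: synthio.SynthConfig | None = None
    site_params: SiteParams = field(default_factory=SiteParams)
    wto_params: WTOParams = field(default_factory=WTOParams)
    de_alpha: float = 0.05
    distance_cut: float = 0.5
    chi2_alpha: float = 0.05
    r_min: float = 0.9
    distortion_cut: float = 10.0
    n_top: int = 1000
    min_counts: float = 200.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synth", None)
        site = raw.pop("site_params", None)
        wtop = raw.pop("wto_params", None)
        cfg = cls(**raw)
        if synth:
            cfg.synth = synthio.SynthConfig(**synth)
        if site:
            cfg.site_params = SiteParams(**site)
        if wtop:
            cfg.wto_params = WTOParams(**wtop)
        return cfg

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def validate_inputs(paths: dict[str, str]) -> dict[str, list[str]]:
    """Sanity-check input files; returns {'fatal': [...], 'warnings': [...]}."""
    report = {"fatal": [], "warnings": []}
    for key, p in paths.items():
        if not Path(p).exists():
            report["fatal"].append(f"{key}: missing file {p}")
    if report["fatal"]:
        return report
    if "annotation" in paths:
        ann = pd.read_csv(paths["annotation"], sep="\t")
        need = {"region_id", "start", "end", "feature", "gene_id"}
        extra = set(ann.columns) - need
        if not need <= set(ann.columns):
            report["fatal"].append("annotation: missing required columns")
        else:
            if (ann["start"] >= ann["end"]).any() or (ann["start"] < 0).any():
                report["fatal"].append("annotation: malformed intervals "
                                       "(expected 0-based half-open)")
            if extra:
                report["warnings"].append(
                    f"annotation: unknown extra columns {sorted(extra)}")
    for key in ("rpkm", "counts"):
        if key in paths:
            try:
                ExpressionMatrix.from_tsv(paths[key])
            except Exception as exc:  # noqa: BLE001 - reported, not raised
                report["fatal"].append(f"{key}: unreadable ({exc})")
    if "atlas" in paths and "rpkm" in paths and not report["fatal"]:
        atlas = synthio.read_atlas(paths["atlas"])
        expr = ExpressionMatrix.from_tsv(paths["rpkm"])
        if len(atlas.index.intersection(expr.genes)) == 0:
            report["fatal"].append("atlas: no gene overlap with expression")
    for key, p in paths.items():
        if key.startswith("pileup"):
            last_end: dict[str, int] = {}
            for line in open(p):
                rid, s, e, _ = line.split("\t")
                s, e = int(s), int(e)
                if s >= e or s < 0:
                    report["fatal"].append(f"{key}: bad interval {rid}:{s}-{e}")
                    break
                if rid in last_end and s < last_end[rid]:
                    report["warnings"].append(f"{key}: unsorted intervals on {rid}")
                    break
                last_end[rid] = e
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    synth_cfg = config.synth or synthio.SynthConfig(seed=config.stage_seed("simulate"))
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "params_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
            .encode()).hexdigest()[:16],
    }

    # ---- inputs -----------------------------------------------------------
    if config.data_dir is not None:
        data_dir = Path(config.data_dir)
        paths = {p.stem: str(p) for p in data_dir.iterdir()}
    elif "simulate" in config.stages:
        data_dir = out / "data"
        paths = synthio.write_bundle(synth_cfg, data_dir)
        manifest["stages"]["simulate"] = {"outputs": paths,
                                          "seed": synth_cfg.seed}
    else:
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1))
        return manifest

    region_lengths = {g: synth_cfg.region_length
                      for g in synthio.annotation_table(synth_cfg)["region_id"].unique()}
    annotation = pd.read_csv(paths["annotation"], sep="\t")
    counts = ExpressionMatrix.from_tsv(paths["counts"])
    rpkm = ExpressionMatrix.from_tsv(paths["rpkm"])
    final_tp = max(counts.timepoints)

    wt_specific_genes: list[str] = []
    de_final: pd.DataFrame | None = None

    # ---- peaks ------------------------------------------------------------
    if "peaks" in config.stages:
        consensus = {}
        tracks_by_cond = {}
        for cond in ("WT", "KO"):
            reps = []
            r = 1
            while f"pileup_{cond}_rep{r}" in paths:
                tracks = read_bedgraph(paths[f"pileup_{cond}_rep{r}"], region_lengths)
                reps.append(tracks)
                r += 1
            per_rep_sites = [
                [s for t in tracks for s in peaks.split_sites(t, config.site_params)]
                for tracks in reps
            ]
            consensus[cond] = peaks.consensus_sites(per_rep_sites)
            tracks_by_cond[cond] = reps
        specific = peaks.condition_specific_sites(consensus["WT"], consensus["KO"])
        specific = peaks.recompute_depth_sums(specific, tracks_by_cond["WT"])
        signals = peaks.annotate_and_normalize(
            specific, annotation, rpkm, condition="WT", timepoint=final_tp)
        sites_to_bed(specific, out / "wt_specific_sites.bed")
        peaks.gene_signal_table(signals).to_csv(
            out / "gene_signal.tsv", sep="\t", index=False)
        wt_specific_genes = [s.gene_id for s in signals
                             if s.normalized_signal is not None]
        manifest["stages"]["peaks"] = {
            "n_consensus_wt": len(consensus["WT"]),
            "n_consensus_ko": len(consensus["KO"]),
            "n_wt_specific": len(specific),
            "outputs": [str(out / "wt_specific_sites.bed"),
                        str(out / "gene_signal.tsv")],
        }

    # ---- targets ----------------------------------------------------------
    if "targets" in config.stages:
        if not wt_specific_genes and (out / "gene_signal.tsv").exists():
            # resume from a previous peaks-stage run
            sig = pd.read_csv(out / "gene_signal.tsv", sep="\t")
            wt_specific_genes = list(
                sig.loc[sig["normalized_signal"].notna(), "gene_id"])
        de_final = targets.de_test(counts, ("WT", "KO"), timepoint=final_tp)
        de_final.to_csv(out / "de_final.tsv", sep="\t", index=False)
        annotated = pd.read_csv(paths["annotated_targets"], sep="\t")["gene_id"]
        calls = targets.intersect_targets(wt_specific_genes, de_final,
                                          annotated, alpha=config.de_alpha)
        targets.calls_table(calls).to_csv(out / "target_calls.tsv",
                                          sep="\t", index=False)
        venn = targets.venn_summary(calls)
        (out / "venn_summary.json").write_text(json.dumps(venn, indent=1))
        manifest["stages"]["targets"] = {
            "venn": venn,
            "high_confidence": targets.high_confidence_targets(calls),
            "outputs": [str(out / "target_calls.tsv"),
                        str(out / "venn_summary.json")],
        }

    # ---- wTO networks -----------------------------------------------------
    networks: dict[tuple[str, int], pd.DataFrame] = {}
    if "wto" in config.stages:
        expressed = wto.filter_expressed(rpkm, config.wto_params.rpkm_min)
        tf_nodes = [g for g in expressed.genes if g.startswith("TF")]
        seed0 = config.stage_seed("wto")
        edge_files = []
        for cond in counts.conditions:
            for tp in counts.timepoints:
                sub = expressed.subset(condition=cond, timepoint=tp)
                links = wto.wto_bootstrap(
                    sub, tf_nodes, config.wto_params,
                    seed=(seed0 + 7919 * tp + (0 if cond == "WT" else 1)) % (2**31))
                kept = wto.significant_links(links, config.wto_params.p_cut)
                networks[(cond, tp)] = kept
                f = out / f"wto_{cond}_day{tp}.tsv"
                kept.to_csv(f, sep="\t", index=False)
                edge_files.append(str(f))
        manifest["stages"]["wto"] = {
            "n_nodes": len(tf_nodes),
            "n_expressed": len(expressed.genes),
            "outputs": edge_files,
        }

    # ---- CoDiNA -----------------------------------------------------------
    if "codina" in config.stages and not networks:
        # resume from previously written edge lists
        for cond in counts.conditions:
            for tp in counts.timepoints:
                f = out / f"wto_{cond}_day{tp}.tsv"
                if f.exists():
                    networks[(cond, tp)] = pd.read_csv(f, sep="\t")
    if "codina" in config.stages and networks:
        summaries = {}
        for tp in counts.timepoints:
            links = codina.classify_links(
                [networks[("WT", tp)], networks[("KO", tp)]],
                distance_cut=config.distance_cut, names=["WT", "KO"])
            links.to_csv(out / f"codina_day{tp}.tsv", sep="\t", index=False)
            calls = codina.classify_nodes(links, alpha=config.chi2_alpha)
            codina.node_table(calls).to_csv(
                out / f"codina_nodes_day{tp}.tsv", sep="\t", index=False)
            summaries[str(tp)] = codina.category_summary(links)
        (out / "codina_summary.json").write_text(json.dumps(summaries, indent=1))
        manifest["stages"]["codina"] = {"category_counts": summaries}

    # ---- SOM --------------------------------------------------------------
    if "som" in config.stages:
        days = [t for t in counts.timepoints if t >= 1]
        de_days = {t: targets.de_test(counts, ("WT", "KO"), timepoint=t)
                   for t in days}
        tf_all = [g for g in counts.genes if g.startswith("TF")]
        nfc = som.persistent_de_tfs(de_days, tf_all, alpha=config.de_alpha)
        if len(nfc) >= 2:
            fit = som.fit_som(nfc, seed=config.stage_seed("som"),
                              distortion_cut=config.distortion_cut)
            member = fit.membership.to_frame("unit")
            member["qerror"] = [
                fit.qerror_per_unit[u] for u in fit.membership]
            member.to_csv(out / "som_membership.tsv", sep="\t",
                          index_label="gene_id")
            som.cluster_summaries(fit, nfc).to_csv(
                out / "som_summaries.tsv", sep="\t", index_label="day")
            manifest["stages"]["som"] = {
                "grid": list(fit.grid),
                "avg_distortion": fit.avg_distortion,
                "n_tfs": len(nfc),
            }
        else:
            manifest["stages"]["som"] = {"n_tfs": len(nfc),
                                         "note": "too few persistent TFs"}

    # ---- atlas ------------------------------------------------------------
    if "atlas" in config.stages:
        atlas = synthio.read_atlas(paths["atlas"])
        top = atlas_mod.top_de_genes(counts, "WT", final_tp, 0,
                                     n_top=config.n_top)
        profile = rpkm.day_means("WT")[final_tp]
        calls = atlas_mod.correlate_to_atlas(profile, atlas, top)
        calls = atlas_mod.call_region_age(calls)
        atlas_mod.calls_table(calls).to_csv(out / "atlas_calls.tsv",
                                            sep="\t", index=False)
        sig = [(c.region, c.age) for c in calls if c.significant]
        manifest["stages"]["atlas"] = {"significant": sig}

    # ---- miRNA ------------------------------------------------------------
    if "mirna" in config.stages:
        wc = pd.read_csv(paths["mirna_wholecell"], sep="\t", index_col=0)
        ip = pd.read_csv(paths["mirna_ip"], sep="\t", index_col=0)
        meta = pd.read_csv(paths["mirna_samples"], sep="\t", index_col=0)
        gt_hk = [i for i in wc.index if i.startswith("HK")]
        norm_wc = mirna.normalize_counts(wc, gt_hk)
        norm_ip = mirna.normalize_counts(ip, gt_hk)
        abundant = mirna.filter_abundant(wc.drop(index=gt_hk), config.min_counts)
        final_m = meta["timepoint"].max()
        # DE on raw counts (depth-matched by design); normalised counts feed
        # the density and activity summaries
        em = lambda tab: ExpressionMatrix(tab, meta)  # noqa: E731
        ip_de = targets.de_test(em(ip), ("WT", "KO"), timepoint=final_m)
        wc_de = targets.de_test(em(wc), ("WT", "KO"), timepoint=final_m)
        cand = mirna.takeover_candidates(ip_de, wc_de, abundant,
                                         alpha=config.de_alpha)
        ip_means = mirna.replicate_means(norm_ip.drop(index=gt_hk), meta)
        wc_means = mirna.replicate_means(norm_wc.drop(index=gt_hk), meta)
        conds = [c for c in ("WT", "KO") if c in meta["condition"].unique()]
        ranks, shifts = mirna.activity_rank(
            ip_means.xs(final_m, axis=1, level="timepoint")[conds],
            wc_means.xs(final_m, axis=1, level="timepoint")[conds])
        ranks.to_csv(out / "mirna_activity.tsv", sep="\t", index=False)
        shifts.to_csv(out / "mirna_rank_shifts.tsv", sep="\t", index=False)
        mirna.density_summary(norm_wc, meta).to_csv(
            out / "mirna_density.tsv", sep="\t", index=False)
        manifest["stages"]["mirna"] = {
            "n_abundant": len(abundant),
            "takeover_candidates": cand,
        }

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    return manifest
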