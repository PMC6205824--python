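"""Seeded generators for every input the pipeline consumes.

Each generator returns the data plus a ground-truth record so downstream
recovery (site recall, target precision/recall, differential-link recall,
trajectory-cluster ARI, atlas block identification) can be scored without
re-deriving what was planted.

The emulated design mirrors the study layout: two cell lines (``WT`` and a
miRNA-knockout ``KO``) followed over five days of induced neurogenesis with
seven biological replicates per condition and day; AGO2-RIP pileups with
three replicates per condition; nCounter-style miRNA count tables in which
one dominant species is ablated in the knockout; and a region x age
developmental expression atlas.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ripnet.containers import ExpressionMatrix, PileupTrack

CONDITIONS = ("WT", "KO")

#: differential-expression trajectory shapes (KO minus WT, units of
#: ``effect_size`` log2) over days 0..4; day 0 is always 0 so that the two
#: conditions are exchangeable before induction.
TRAJECTORY_SHAPES = {
    "rising": np.array([0.0, 1.33, 1.89, 2.44, 3.0]),
    "falling": -np.array([0.0, 1.33, 1.89, 2.44, 3.0]),
    "early": np.array([0.0, 3.0, 2.44, 1.89, 1.33]),
}
_SHAPE_CYCLE = ("rising", "falling", "early")


@dataclass
class SynthConfig:
    """All knobs of the synthetic study, with the emulated design as defaults."""

    seed: int = 0

    # AGO2-RIP pileups
    n_regions: int = 60
    region_length: int = 1000
    n_replicates_pileup: int = 3
    background_rate: float = 0.5      # Poisson mean reads/base
    site_height: float = 40.0         # summit reads of planted sites
    site_width: int = 61              # bases (odd: symmetric triangle)

    # expression time course
    n_genes: int = 300
    n_tfs: int = 30
    n_timepoints: int = 5             # days 0..4 post induction
    n_replicates_expr: int = 7
    effect_size: float = 1.5          # log2 fold units for planted targets
    noise_dispersion: float = 0.10    # log-normal sigma (log2) for RPKM
    nb_dispersion: float = 0.05       # NB dispersion for raw counts
    n_modules: int = 6
    members_per_module: int = 15
    module_loading: float = 0.6       # TF latent-factor loading (log2 units)
    member_loading: float = 2.0       # member-gene loading (log2 units)
    diff_module_loading: float = 0.75  # TF loading of the rewired modules
    n_targets: int = 20
    n_low_expressed: int = 30         # genes kept below the RPKM floor
    plant_rewiring: bool = True

    # miRNA tables
    n_mirnas: int = 40
    n_housekeeping: int = 5
    n_takeover: int = 3
    dominant_fraction: float = 0.8    # dominant miRNA share of WT counts, final day
    mirna_timepoints: tuple[int, ...] = (0, 4)
    n_replicates_mirna: int = 3

    # atlas
    n_atlas_regions: int = 5
    n_atlas_ages: int = 8
    atlas_noise: float = 0.2

    def __post_init__(self) -> None:
        if self.site_width >= self.region_length:
            raise ValueError("site_width must be smaller than region_length")
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs cannot exceed n_genes")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for name in ("n_regions", "region_length", "n_replicates_pileup",
                     "n_genes", "n_tfs", "n_timepoints", "n_replicates_expr"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_timepoints < 2:
            raise ValueError("need at least two timepoints")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one named stream, derived from the seed."""
        tag = zlib.crc32(stream.encode()) % (2**31)
        ss = np.random.SeedSequence([int(self.seed) % (2**31), tag])
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    planted_sites: list[dict] = field(default_factory=list)
    boundary_sites: list[dict] = field(default_factory=list)
    planted_targets: list[str] = field(default_factory=list)
    planted_modules: dict[str, dict] = field(default_factory=dict)
    planted_diff_links: list[tuple[str, str]] = field(default_factory=list)
    planted_clusters: dict[str, str] = field(default_factory=dict)
    dominant_mirna: str = ""
    takeover_mirnas: list[str] = field(default_factory=list)
    housekeeping: list[str] = field(default_factory=list)
    atlas_block: tuple[str, int] | None = None
    low_expressed: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        gt = cls(**raw)
        gt.planted_diff_links = [tuple(p) for p in gt.planted_diff_links]
        if gt.atlas_block is not None:
            gt.atlas_block = (gt.atlas_block[0], int(gt.atlas_block[1]))
        return gt


# ---------------------------------------------------------------------------
# gene naming

def gene_ids(cfg: SynthConfig) -> list[str]:
    """TFs first (``TF001``..), then plain genes (``G0031``..)."""
    tfs = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    rest = [f"G{i + 1:04d}" for i in range(cfg.n_tfs, cfg.n_genes)]
    return tfs + rest


def _gene_roles(cfg: SynthConfig) -> dict[str, list[str]]:
    """Deterministic partition of the gene namespace into planted roles."""
    ids = gene_ids(cfg)
    tfs = ids[: cfg.n_tfs]
    rest = ids[cfg.n_tfs:]
    n_members = cfg.n_modules * cfg.members_per_module
    members = rest[:n_members]
    targets = rest[n_members: n_members + cfg.n_targets]
    low = rest[n_members + cfg.n_targets:
               n_members + cfg.n_targets + cfg.n_low_expressed]
    return {"tfs": tfs, "members": members, "targets": targets, "low": low}


# ---------------------------------------------------------------------------
# pileups


def _triangle(height: float, width: int) -> np.ndarray:
    """Isoceles triangular bump with linear flanks, peak at the centre."""
    half = width // 2
    flank = np.arange(1, half + 1) / (half + 1)
    return height * np.concatenate([flank, [1.0], flank[::-1]])


def gen_pileups(cfg: SynthConfig) -> tuple[dict[str, dict[int, list[PileupTrack]]], GroundTruth]:
    """Replicated AGO2-RIP coverage with planted binding sites.

    Returns ``tracks[condition][replicate] -> list of PileupTrack`` (one per
    region) and the ground truth.  Regions are named after genes: the first
    third carry a WT-specific site inside the annotated 3'UTR (the planted
    miRNA targets), the second third carry a condition-shared 3'UTR site, and
    the last third carry only boundary-height decoys or pure background.
    """
    roles = _gene_roles(cfg)
    region_genes = (roles["targets"]
                    + roles["members"][: cfg.n_regions - cfg.n_targets])
    region_genes = region_genes[: cfg.n_regions]
    gt = GroundTruth(planted_targets=list(roles["targets"]))

    utr_start = int(cfg.region_length * 0.6)  # 3'UTR = last 40% of the region
    centre = (utr_start + cfg.region_length) // 2
    plans: dict[str, list[tuple[int, float, str]]] = {g: [] for g in region_genes}

    n_shared = max(0, min(len(region_genes) - cfg.n_targets,
                          cfg.n_targets))
    shared_genes = region_genes[cfg.n_targets: cfg.n_targets + n_shared]
    decoy_genes = region_genes[cfg.n_targets + n_shared:]

    if cfg.site_height > 0:
        for g in roles["targets"]:
            plans[g].append((centre, cfg.site_height, "WT"))
            gt.planted_sites.append(
                {"region_id": g,
                 "start": centre - cfg.site_width // 2,
                 "end": centre + cfg.site_width // 2 + 1,
                 "height": cfg.site_height,
                 "specificity": "WT"})
        for g in shared_genes:
            plans[g].append((centre, cfg.site_height, "both"))
            gt.planted_sites.append(
                {"region_id": g,
                 "start": centre - cfg.site_width // 2,
                 "end": centre + cfg.site_width // 2 + 1,
                 "height": cfg.site_height,
                 "specificity": "both"})
        # decoys straddling the 10-read background rule
        for i, g in enumerate(decoy_genes):
            h = (8, 9, 11, 12)[i % 4]
            pos = cfg.region_length // 4
            plans[g].append((pos, float(h), "both"))
            gt.boundary_sites.append(
                {"region_id": g, "start": pos - cfg.site_width // 2,
                 "end": pos + cfg.site_width // 2 + 1,
                 "height": float(h), "specificity": "both"})

    rng = cfg.rng("pileups")
    tracks: dict[str, dict[int, list[PileupTrack]]] = {}
    for cond in CONDITIONS:
        tracks[cond] = {}
        for rep in range(1, cfg.n_replicates_pileup + 1):
            reg_tracks = []
            for g in region_genes:
                depth = rng.poisson(cfg.background_rate, cfg.region_length).astype(float)
                for pos, h, spec in plans[g]:
                    if spec == "WT" and cond != "WT":
                        continue
                    bump = _triangle(h, cfg.site_width)
                    lo = pos - cfg.site_width // 2
                    depth[lo: lo + len(bump)] += np.round(bump)
                reg_tracks.append(
                    PileupTrack(g, 0, cfg.region_length, depth.astype(int)))
            tracks[cond][rep] = reg_tracks
    return tracks, gt


def annotation_table(cfg: SynthConfig) -> pd.DataFrame:
    """Interval annotation for the pileup regions (transcript + 3'UTR rows)."""
    roles = _gene_roles(cfg)
    region_genes = (roles["targets"]
                    + roles["members"][: cfg.n_regions - cfg.n_targets])
    utr_start = int(cfg.region_length * 0.6)
    rows = []
    for g in region_genes[: cfg.n_regions]:
        rows.append((g, 0, cfg.region_length, "transcript", g))
        rows.append((g, utr_start, cfg.region_length, "three_prime_UTR", g))
    return pd.DataFrame(
        rows, columns=["region_id", "start", "end", "feature", "gene_id"])


def annotated_target_list(cfg: SynthConfig) -> list[str]:
    """Synthetic stand-in for a database-derived annotated-target list.

    Contains every planted target plus decoy annotated genes that are not
    targets (member genes), so the annotation flag alone is not sufficient.
    """
    roles = _gene_roles(cfg)
    return sorted(roles["targets"] + roles["members"][:30])


# ---------------------------------------------------------------------------
# expression time course


def gen_expression(cfg: SynthConfig) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Two-condition five-day seven-replicate course with planted structure.

    Returns ``(counts, rpkm, ground_truth)``.  Planted structure:

    * ``n_modules`` TF modules; each module's TFs and member genes load on a
      per-sample latent factor, giving within-module |Pearson r| > 0.9 at the
      default noise level.
    * module 0 is rewired in the knockout from day 1 on by sign-flipping the
      loadings of two of its TFs (links flip sign: "different" links);
      module 1 is silenced in the knockout (loadings set to 0: WT-specific
      links).  Disabled when ``plant_rewiring`` is False.
    * modules carry distinct differential-expression trajectory shapes
      (rising / falling / early-transient, scaled by ``effect_size``) so
      their TFs are persistently DE on days 1..4.
    * planted target genes get a ``+effect_size`` log2 shift in KO from day 1.
    * a block of genes stays below the expression floor on every day.

    Both conditions are exchangeable draws at day 0.
    """
    if cfg.n_timepoints != len(next(iter(TRAJECTORY_SHAPES.values()))):
        shapes = {k: np.interp(np.linspace(0, 4, cfg.n_timepoints),
                               np.arange(5), v)
                  for k, v in TRAJECTORY_SHAPES.items()}
        for k in shapes:
            shapes[k][0] = 0.0
    else:
        shapes = TRAJECTORY_SHAPES

    roles = _gene_roles(cfg)
    ids = gene_ids(cfg)
    rng = cfg.rng("expression")
    gt = GroundTruth(planted_targets=list(roles["targets"]),
                     low_expressed=list(roles["low"]))

    tfs_per_module = cfg.n_tfs // cfg.n_modules
    modules = []
    for m in range(cfg.n_modules):
        tf_block = roles["tfs"][m * tfs_per_module: (m + 1) * tfs_per_module]
        mem_block = roles["members"][m * cfg.members_per_module:
                                     (m + 1) * cfg.members_per_module]
        shape = _SHAPE_CYCLE[m % len(_SHAPE_CYCLE)]
        rewiring = "none"
        if cfg.plant_rewiring and m == 0:
            rewiring = "sign_flip"
        elif cfg.plant_rewiring and m == 1:
            rewiring = "silenced"
        modules.append({"tfs": tf_block, "members": mem_block,
                        "shape": shape, "rewiring": rewiring})
        gt.planted_modules[f"M{m}"] = modules[-1]
        for tf in tf_block:
            gt.planted_clusters[tf] = shape
    if cfg.plant_rewiring:
        flip = modules[0]["tfs"][:2]
        keep = modules[0]["tfs"][2:]
        gt.planted_diff_links = [(a, b) for a in flip for b in keep]
        sil = modules[1]["tfs"]
        gt.planted_diff_links += [(sil[i], sil[j])
                                  for i in range(len(sil))
                                  for j in range(i + 1, len(sil))]

    base = pd.Series(rng.uniform(4.0, 9.0, cfg.n_genes), index=ids)  # log2 RPKM
    base[roles["low"]] = rng.uniform(-1.0, 1.5, len(roles["low"]))  # RPKM 0.5..2.8

    cols, meta, log2 = [], [], []
    for cond in CONDITIONS:
        for t in range(cfg.n_timepoints):
            for rep in range(1, cfg.n_replicates_expr + 1):
                sample = f"{cond}_t{t}_r{rep}"
                x = base.copy()
                # latent module factors, one draw per sample
                for m, mod in enumerate(modules):
                    f = rng.normal()
                    lam_tf = (cfg.diff_module_loading
                              if mod["rewiring"] != "none" else cfg.module_loading)
                    active = cond == "WT" or t == 0 or mod["rewiring"] != "silenced"
                    for g in mod["tfs"] + mod["members"]:
                        l_g = lam_tf if g in mod["tfs"] else cfg.member_loading
                        if (mod["rewiring"] == "sign_flip" and cond == "KO"
                                and t >= 1 and g in mod["tfs"][:2]):
                            l_g = -l_g
                        if not active:
                            l_g = 0.0
                        x[g] = x[g] + l_g * f
                # DE trajectories on TFs, target shift, in KO only
                if cond == "KO" and t >= 1:
                    for mod in modules:
                        delta = cfg.effect_size * shapes[mod["shape"]][t]
                        x[mod["tfs"]] = x[mod["tfs"]] + delta
                    x[roles["targets"]] = x[roles["targets"]] + cfg.effect_size
                x = x + rng.normal(0.0, cfg.noise_dispersion, cfg.n_genes)
                cols.append(sample)
                meta.append((cond, t, rep))
                log2.append(x.to_numpy())

    log2 = pd.DataFrame(np.column_stack(log2), index=ids, columns=cols)
    samples = pd.DataFrame(meta, columns=["condition", "timepoint", "replicate"],
                           index=cols)
    rpkm_vals = np.power(2.0, log2)
    rpkm = ExpressionMatrix(rpkm_vals.round(4), samples.copy())

    # raw counts: NB around RPKM x depth factor, matching RNA-seq overdispersion
    mean_counts = rpkm_vals.to_numpy() * 10.0
    r = 1.0 / max(cfg.nb_dispersion, 1e-8)
    p = r / (r + mean_counts)
    counts_vals = rng.negative_binomial(r, p)
    counts = ExpressionMatrix(
        pd.DataFrame(counts_vals, index=ids, columns=cols), samples.copy())
    return counts, rpkm, gt


# ---------------------------------------------------------------------------
# miRNA tables


def gen_mirna_counts(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """nCounter-style whole-cell and AGO2-IP miRNA count tables.

    Returns ``(wholecell, ip, sample_meta, gt)``.  The dominant species holds
    ~``dominant_fraction`` of WT counts at the final day and is absent from
    the knockout at every day; ``n_takeover`` species are up-regulated in the
    knockout in both whole-cell and IP counts.  Housekeeping rows have
    condition-independent means.
    """
    if cfg.n_housekeeping < 1:
        raise ValueError("housekeeping set must not be empty")
    rng = cfg.rng("mirna")
    mirnas = [f"miR-{i + 1:03d}" for i in range(cfg.n_mirnas)]
    hk = [f"HK-{i + 1}" for i in range(cfg.n_housekeeping)]
    gt = GroundTruth(dominant_mirna=mirnas[0],
                     takeover_mirnas=mirnas[1: 1 + cfg.n_takeover],
                     housekeeping=hk)

    base = rng.uniform(300, 2000, cfg.n_mirnas)
    base[1: 1 + cfg.n_takeover] = rng.uniform(400, 1200, cfg.n_takeover)
    hk_base = rng.uniform(800, 1200, cfg.n_housekeeping)
    # per-species RISC affinity: IP signal = whole-cell x affinity, identical
    # in both conditions, geometrically spaced so the activity ranking is a
    # stable property of the species rather than of counting noise
    affinity = 0.8 * 1.15 ** np.arange(cfg.n_mirnas)
    affinity = affinity[rng.permutation(cfg.n_mirnas)]

    final = max(cfg.mirna_timepoints)
    cols, meta = [], []
    wc, ip = [], []
    for cond in CONDITIONS:
        for t in cfg.mirna_timepoints:
            for rep in range(1, cfg.n_replicates_mirna + 1):
                cols.append(f"{cond}_t{t}_r{rep}")
                meta.append((cond, t, rep))
                mu = base.copy()
                ramp = t / final if final else 0.0
                if cond == "WT":
                    # dominant species ramps up to dominant_fraction of counts
                    rest = base[1:].sum()
                    mu[0] = ramp * cfg.dominant_fraction * rest / (1 - cfg.dominant_fraction)
                else:
                    mu[0] = 0.0
                    mu[1: 1 + cfg.n_takeover] *= 1.0 + 2.0 * ramp  # takeover
                wc_mu = np.concatenate([mu, hk_base])
                wc.append(rng.poisson(wc_mu))
                ip_mu = np.concatenate([mu * affinity, hk_base])
                if cond == "KO":
                    ip_mu[1: 1 + cfg.n_takeover] *= 1.5  # enhanced RISC loading
                ip.append(rng.poisson(ip_mu))

    index = mirnas + hk
    sample_meta = pd.DataFrame(meta, columns=["condition", "timepoint", "replicate"],
                               index=cols)
    wholecell = pd.DataFrame(np.column_stack(wc), index=index, columns=cols)
    ip_tab = pd.DataFrame(np.column_stack(ip), index=index, columns=cols)
    return wholecell, ip_tab, sample_meta, gt


# ---------------------------------------------------------------------------
# atlas


def gen_atlas(cfg: SynthConfig, rpkm: ExpressionMatrix | None = None
              ) -> tuple[pd.DataFrame, GroundTruth]:
    """Block-structured region x age expression atlas (FPKM-like).

    Columns are a (region, age) MultiIndex.  Each region follows its own
    smooth age drift; one designated block is built from the WT final-day
    mean profile of the expression course (generated on the fly when ``rpkm``
    is not supplied), so an atlas query with that profile resolves uniquely.
    """
    if rpkm is None:
        _, rpkm, _ = gen_expression(cfg)
    rng = cfg.rng("atlas")
    genes = rpkm.genes
    final = max(rpkm.timepoints)
    template = np.log2(rpkm.day_means("WT")[final].to_numpy() + 1.0)

    regions = [f"region{r + 1}" for r in range(cfg.n_atlas_regions)]
    ages = list(range(1, cfg.n_atlas_ages + 1))
    block_region = regions[cfg.n_atlas_regions // 2]
    block_age = ages[cfg.n_atlas_ages // 2]
    gt = GroundTruth(atlas_block=(block_region, block_age))

    cols = {}
    for r_i, region in enumerate(regions):
        region_profile = rng.uniform(0.0, 9.0, len(genes))
        drift = rng.normal(0.0, 0.3, len(genes))
        for age in ages:
            col = region_profile + drift * age + rng.normal(0.0, cfg.atlas_noise, len(genes))
            if region == block_region and age == block_age:
                col = template + rng.normal(0.0, cfg.atlas_noise, len(genes))
            cols[(region, age)] = np.power(2.0, col) - 1.0
    atlas = pd.DataFrame(cols, index=genes)
    atlas.columns = pd.MultiIndex.from_tuples(atlas.columns, names=["region", "age"])
    return atlas.clip(lower=0.0).round(4), gt


# ---------------------------------------------------------------------------
# bundle writer


def write_bundle(cfg: SynthConfig, outdir: str | Path) -> dict[str, str]:
    """Generate every input and write it under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    tracks, gt_sites = gen_pileups(cfg)
    for cond, reps in tracks.items():
        for rep, tlist in reps.items():
            p = outdir / f"pileup_{cond}_rep{rep}.bedgraph"
            with open(p, "w") as fh:
                for t in tlist:
                    t.to_bedgraph(fh)
            paths[f"pileup_{cond}_rep{rep}"] = str(p)

    counts, rpkm, gt_expr = gen_expression(cfg)
    counts.to_tsv(outdir / "counts.tsv")
    rpkm.to_tsv(outdir / "rpkm.tsv")
    paths["counts"] = str(outdir / "counts.tsv")
    paths["rpkm"] = str(outdir / "rpkm.tsv")

    ann = annotation_table(cfg)
    ann.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    paths["annotation"] = str(outdir / "annotation.tsv")
    pd.Series(annotated_target_list(cfg)).to_csv(
        outdir / "annotated_targets.tsv", index=False, header=["gene_id"])
    paths["annotated_targets"] = str(outdir / "annotated_targets.tsv")

    wc, ip, mmeta, gt_mirna = gen_mirna_counts(cfg)
    wc.to_csv(outdir / "mirna_wholecell.tsv", sep="\t")
    ip.to_csv(outdir / "mirna_ip.tsv", sep="\t")
    mmeta.to_csv(outdir / "mirna_samples.tsv", sep="\t")
    paths.update(mirna_wholecell=str(outdir / "mirna_wholecell.tsv"),
                 mirna_ip=str(outdir / "mirna_ip.tsv"),
                 mirna_samples=str(outdir / "mirna_samples.tsv"))

    atlas, gt_atlas = gen_atlas(cfg, rpkm)
    atlas.to_csv(outdir / "atlas.tsv", sep="\t")
    paths["atlas"] = str(outdir / "atlas.tsv")

    gt = GroundTruth(
        planted_sites=gt_sites.planted_sites,
        boundary_sites=gt_sites.boundary_sites,
        planted_targets=gt_expr.planted_targets,
        planted_modules=gt_expr.planted_modules,
        planted_diff_links=gt_expr.planted_diff_links,
        planted_clusters=gt_expr.planted_clusters,
        dominant_mirna=gt_mirna.dominant_mirna,
        takeover_mirnas=gt_mirna.takeover_mirnas,
        housekeeping=gt_mirna.housekeeping,
        atlas_block=gt_atlas.atlas_block,
        low_expressed=gt_expr.low_expressed,
    )
    gt.to_json(outdir / "ground_truth.json")
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths


def read_atlas(path: str | Path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    atlas.columns = pd.MultiIndex.from_tuples(
        [(r, int(a)) for r, a in atlas.columns], names=["region", "age"])
    return atlas
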