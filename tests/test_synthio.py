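"""Generator contracts: determinism, degenerate cases, planted structure."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ripnet import mirna
from ripnet.synthio import (SynthConfig, gen_atlas, gen_expression, gen_mirna_counts,
                            gen_pileups, annotation_table, annotated_target_list)


def _all_depths(tracks):
    return np.concatenate([t.depth for cond in tracks.values()
                           for rep in cond.values() for t in rep])


def test_generators_are_deterministic_under_fixed_seed():
    a, b = SynthConfig(seed=1), SynthConfig(seed=1)
    ta, _ = gen_pileups(a)
    tb, _ = gen_pileups(b)
    assert np.array_equal(_all_depths(ta), _all_depths(tb))
    ca, ra, _ = gen_expression(a)
    cb, rb, _ = gen_expression(b)
    pd.testing.assert_frame_equal(ca.values, cb.values)
    pd.testing.assert_frame_equal(ra.values, rb.values)
    wa, ia, ma, _ = gen_mirna_counts(a)
    wb, ib, mb, _ = gen_mirna_counts(b)
    pd.testing.assert_frame_equal(wa, wb)
    pd.testing.assert_frame_equal(ia, ib)
    xa, _ = gen_atlas(a, ra)
    xb, _ = gen_atlas(b, rb)
    pd.testing.assert_frame_equal(xa, xb)


def test_different_seeds_differ():
    ta, _ = gen_pileups(SynthConfig(seed=1))
    tb, _ = gen_pileups(SynthConfig(seed=2))
    assert not np.array_equal(_all_depths(ta), _all_depths(tb))


def test_zero_site_height_gives_pure_poisson_background():
    cfg = SynthConfig(seed=3, site_height=0.0)
    tracks, gt = gen_pileups(cfg)
    assert gt.planted_sites == []
    depths = _all_depths(tracks)
    # Poisson(0.5): mean within a few SE
    assert abs(depths.mean() - 0.5) < 0.02


def test_zero_background_confines_depth_to_planted_sites():
    cfg = SynthConfig(seed=3, background_rate=0.0)
    tracks, gt = gen_pileups(cfg)
    planted = {}
    for p in gt.planted_sites + gt.boundary_sites:
        planted.setdefault(p["region_id"], []).append((p["start"], p["end"]))
    for t in tracks["WT"][1]:
        mask = np.zeros(len(t.depth), bool)
        for a, b in planted.get(t.region_id, []):
            mask[a:b] = True
        assert not np.any(t.depth[~mask] > 0)


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SynthConfig(site_width=1000, region_length=1000)
    with pytest.raises(ValueError):
        SynthConfig(n_tfs=500, n_genes=300)
    with pytest.raises(ValueError):
        SynthConfig(n_timepoints=1)
    with pytest.raises(ValueError):
        gen_mirna_counts(SynthConfig(n_housekeeping=0))


def test_within_module_correlation_exceeds_point_nine(expression_data):
    """Module structure is stationary in WT, so pool WT samples for a tight
    estimate of the within-module correlation the generator promises."""
    _, rpkm, gt = expression_data
    logx = np.log2(rpkm.subset("WT").values + 1e-9)
    for m in ("M2", "M3", "M4", "M5"):
        tfs = gt.planted_modules[m]["tfs"]
        corr = np.corrcoef(logx.loc[tfs].to_numpy())
        off = corr[np.triu_indices(len(tfs), 1)]
        assert np.abs(off).min() > 0.9, m


def test_noise_free_limit_gives_perfect_module_correlation():
    cfg = SynthConfig(seed=5, noise_dispersion=1e-9)
    _, rpkm, gt = gen_expression(cfg)
    sub = rpkm.subset("WT", 1)
    tfs = gt.planted_modules["M3"]["tfs"]
    corr = np.corrcoef(np.log2(sub.values.loc[tfs].to_numpy()))
    off = corr[np.triu_indices(len(tfs), 1)]
    assert np.all(np.abs(off) > 1 - 1e-6)


def test_null_configuration_makes_conditions_exchangeable():
    """With effect 0 and no rewiring, KO vs WT DE finds ~nothing."""
    from ripnet.targets import de_test

    cfg = SynthConfig(seed=9, effect_size=0.0, plant_rewiring=False)
    counts, _, gt = gen_expression(cfg)
    assert gt.planted_diff_links == []
    de = de_test(counts, ("WT", "KO"), timepoint=4)
    assert (de["padj"] < 0.05).sum() <= max(3, 0.02 * len(de))


def test_conditions_identical_at_day_zero(expression_data):
    counts, _, _ = expression_data
    de_rows = []
    from ripnet.targets import de_test

    de0 = de_test(counts, ("WT", "KO"), timepoint=0)
    assert (de0["padj"] < 0.05).sum() <= 3


def test_ko_dominant_mirna_is_zero_everywhere(mirna_data):
    wc, ip, meta, gt = mirna_data
    ko_cols = meta.index[meta["condition"] == "KO"]
    assert (wc.loc[gt.dominant_mirna, ko_cols] == 0).all()
    assert (ip.loc[gt.dominant_mirna, ko_cols] == 0).all()


def test_dominant_mirna_share_at_final_day(mirna_data):
    wc, _, meta, gt = mirna_data
    final = meta["timepoint"].max()
    cols = meta.index[(meta["condition"] == "WT") & (meta["timepoint"] == final)]
    share = (wc.loc[gt.dominant_mirna, cols].sum()
             / wc.drop(index=gt.housekeeping)[cols].to_numpy().sum())
    assert share == pytest.approx(0.8, abs=0.05)


def test_day_zero_normalized_counts_indistinguishable(mirna_data):
    wc, _, meta, gt = mirna_data
    norm = mirna.normalize_counts(wc, gt.housekeeping)
    t0 = meta["timepoint"] == 0
    wt = norm.loc[:, meta.index[t0 & (meta["condition"] == "WT")]]
    ko = norm.loc[:, meta.index[t0 & (meta["condition"] == "KO")]]
    keep = norm.index.difference([gt.dominant_mirna])
    p = stats.ks_2samp(np.log1p(wt.loc[keep]).to_numpy().ravel(),
                       np.log1p(ko.loc[keep]).to_numpy().ravel()).pvalue
    assert p > 0.05


def test_atlas_block_matches_its_template_best(expression_data, cfg):
    _, rpkm, _ = expression_data
    atlas, gt = gen_atlas(cfg, rpkm)
    final = max(rpkm.timepoints)
    template = np.log2(rpkm.day_means("WT")[final].to_numpy() + 1.0)
    rs = {col: stats.pearsonr(template,
                              np.log2(atlas[col].to_numpy() + 1.0)).statistic
          for col in atlas.columns}
    best = max(rs, key=rs.get)
    assert (best[0], int(best[1])) == gt.atlas_block


def test_planted_ids_exist_in_emitted_data(expression_data, pileup_data, cfg):
    counts, _, gt = expression_data
    genes = set(counts.genes)
    assert set(gt.planted_targets) <= genes
    assert set(gt.planted_clusters) <= genes
    for a, b in gt.planted_diff_links:
        assert a in genes and b in genes
        assert a.startswith("TF") and b.startswith("TF")
    tracks, gts = pileup_data
    region_ids = {t.region_id for t in tracks["WT"][1]}
    assert {p["region_id"] for p in gts.planted_sites} <= region_ids
    ann = annotation_table(cfg)
    assert set(gts.planted_targets) <= set(ann["gene_id"])
    assert set(gt.planted_targets) <= set(annotated_target_list(cfg))
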