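"""Recovery and calibration checks over planted ground truth.

Each function re-runs part of the pipeline on generated data and measures
how well the planted structure is recovered (or how well a null is
calibrated).  They back both the acceptance test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import json
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from ripnet import codina, peaks, targets, wto
from ripnet.containers import ExpressionMatrix, PileupTrack
from ripnet.pipeline import PipelineConfig, run_pipeline
from ripnet.synthio import SynthConfig
from ripnet.wto import WTOParams, wto_from_correlation

#: SOM distortion cut used for z-scored nFC trajectories throughout the
#: analysis (see docs/methods.md for the noise-floor rationale).
NFC_DISTORTION_CUT = 0.2


# ---------------------------------------------------------------------------
# 1. peak splitter vs brute-force oracle


def _oracle_runs(depth, lo, hi, thr):
    out, start = [], None
    for i in range(lo, hi):
        if depth[i] >= thr:
            if start is None:
                start = i
        elif start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, hi))
    return out


def _oracle_recurse(depth, lo, hi, f_sub, tau):
    s = max(depth[lo:hi])
    pieces = _oracle_runs(depth, lo, hi, f_sub * s)
    if pieces == [(lo, hi)]:
        return [(lo, hi, s)]
    out = []
    for a, b in pieces:
        if max(depth[a:b]) >= tau:
            out.extend(_oracle_recurse(depth, a, b, f_sub, tau))
    return out


def oracle_split(depth, tau=10.0, f_primary=0.20, f_sub=0.05):
    """Plain-python reference splitter, independent of :mod:`ripnet.peaks`."""
    depth = list(map(float, depth))
    sites = []
    for lo, hi in _oracle_runs(depth, 0, len(depth), 1e-12):
        s = max(depth[lo:hi])
        if s < tau:
            continue
        for a, b in _oracle_runs(depth, lo, hi, f_primary * s):
            if max(depth[a:b]) >= max(f_primary * s, tau):
                sites.extend(_oracle_recurse(depth, a, b, f_sub, tau))
    return sorted(sites)


def random_pileup_track(rng, max_length=500):
    length = int(rng.integers(10, max_length))
    kind = int(rng.integers(3))
    if kind == 0:
        depth = rng.poisson(rng.uniform(0.2, 6.0), length)
    elif kind == 1:
        depth = rng.integers(0, 100, length)
    else:
        depth = rng.poisson(0.3, length)
        for _ in range(int(rng.integers(1, 6))):
            c = int(rng.integers(0, length))
            w = int(rng.integers(3, 40))
            h = rng.uniform(5, 100)
            for i in range(max(0, c - w), min(length, c + w + 1)):
                depth[i] += int(h * max(0.0, 1 - abs(i - c) / (w + 1)))
    return PileupTrack("chr", 0, length, depth.astype(int))


def splitter_oracle_check(n_tracks=1000, seed=11):
    """Compare split_sites with the reference splitter on random tracks."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    n_sites = 0
    min_summit = np.inf
    for _ in range(n_tracks):
        track = random_pileup_track(rng)
        got = sorted((int(s.start), int(s.end), float(s.summit_height))
                     for s in peaks.split_sites(track))
        expected = sorted(oracle_split(track.depth))
        if got != expected:
            mismatches += 1
        n_sites += len(got)
        if got:
            min_summit = min(min_summit, min(s[2] for s in got))
    return {"mismatches": mismatches, "n_tracks": n_tracks,
            "n_sites": n_sites,
            "min_summit": float(min_summit) if n_sites else None}


# ---------------------------------------------------------------------------
# 2. wTO oracle + bounds


def oracle_wto(corr, nodes):
    """Triple-loop literal evaluation of the signed wTO definition."""
    G = corr.shape[0]
    n = len(nodes)
    omega = np.zeros((n, n))
    for a, i in enumerate(nodes):
        for b, j in enumerate(nodes):
            if i == j:
                continue
            num = sum(corr[i, u] * corr[u, j] for u in range(G)
                      if u not in (i, j)) + corr[i, j]
            k_i = sum(abs(corr[i, u]) for u in range(G) if u != i)
            k_j = sum(abs(corr[j, u]) for u in range(G) if u != j)
            omega[a, b] = num / (min(k_i, k_j) + 1 - abs(corr[i, j]))
    return omega


def wto_oracle_check(n_instances=50, seed=2):
    """Max |difference| between wto and the triple-loop oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        g = int(rng.integers(4, 21))
        n_nodes = int(rng.integers(2, min(7, g + 1)))
        corr = np.corrcoef(rng.normal(size=(g, int(rng.integers(4, 12)))))
        nodes = list(rng.choice(g, size=n_nodes, replace=False))
        diff = np.abs(wto_from_correlation(corr, nodes) - oracle_wto(corr, nodes))
        worst = max(worst, float(diff.max()))
    return {"max_abs_diff": worst, "n_instances": n_instances}


def wto_bound_check(n_trials=10_000, seed=4):
    """Max |omega| over random correlation structures (must be <= 1)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        g = int(rng.integers(3, 12))
        corr = np.corrcoef(rng.normal(size=(g, int(rng.integers(3, 10)))))
        omega = wto_from_correlation(corr, list(range(min(g, 4))))
        worst = max(worst, float(np.abs(omega).max()))
        if not np.allclose(omega, omega.T, atol=1e-12):
            raise AssertionError("wTO asymmetry detected")
    return {"max_abs_omega": worst, "n_trials": n_trials}


# ---------------------------------------------------------------------------
# 3. bootstrap null calibration


def bootstrap_null_calibration(n_repeats=200, n_tfs=10, n_background=50,
                               n_samples=7, n_bootstrap=200, p_cut=0.10,
                               seed=1):
    """Retained-link fraction on independent Gaussian data."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_tfs + n_background)]
    nodes = genes[:n_tfs]
    kept = 0
    total = 0
    params = WTOParams(n_bootstrap=n_bootstrap, p_cut=p_cut)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_repeats):
            x = rng.normal(size=(len(genes), n_samples))
            cols = [f"s{j}" for j in range(n_samples)]
            em = ExpressionMatrix(
                pd.DataFrame(x, index=genes, columns=cols),
                pd.DataFrame({"condition": "null", "timepoint": 0,
                              "replicate": range(1, n_samples + 1)}, index=cols))
            links = wto.wto_bootstrap(em, nodes, params,
                                      seed=int(rng.integers(2**31)))
            kept += int((links["pval"] <= p_cut).sum())
            total += len(links)
    frac = kept / total
    sd = float(np.sqrt(p_cut * (1 - p_cut) / total))
    return {"retained_fraction": frac, "n_links": total,
            "binomial_sd": sd, "band": (p_cut - 3 * sd, p_cut + 3 * sd)}


# ---------------------------------------------------------------------------
# 5. end-to-end planted-truth recovery


def end_to_end_recovery(seed=7, outdir=None, n_bootstrap=1000):
    """Run the whole pipeline on the default synthetic study and score it."""
    tmp = None
    if outdir is None:
        tmp = tempfile.TemporaryDirectory()
        outdir = tmp.name
    try:
        cfg = PipelineConfig(
            seed=seed, outdir=str(outdir), synth=SynthConfig(seed=seed),
            wto_params=WTOParams(n_bootstrap=n_bootstrap),
            distortion_cut=NFC_DISTORTION_CUT)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            manifest = run_pipeline(cfg)
        out = Path(outdir)
        gt = json.loads((out / "data" / "ground_truth.json").read_text())

        hc = set(manifest["stages"]["targets"]["high_confidence"])
        tgt = set(gt["planted_targets"])
        precision = len(hc & tgt) / len(hc) if hc else 0.0
        recall = len(hc & tgt) / len(tgt)

        diff = {tuple(sorted(map(str, p))) for p in gt["planted_diff_links"]}
        found = set()
        days = [t for t in range(1, 10) if (out / f"codina_day{t}.tsv").exists()]
        for d in days:
            kl = pd.read_csv(out / f"codina_day{d}.tsv", sep="\t")
            kl = kl[kl["kept"] & kl["category"].isin(["beta", "gamma"])]
            found |= {tuple(sorted((r.node_i, r.node_j)))
                      for r in kl.itertuples()} & diff
        diff_recall = len(found) / len(diff)

        member = pd.read_csv(out / "som_membership.tsv", sep="\t", index_col=0)
        labels = [gt["planted_clusters"][g] for g in member.index]
        ari = float(adjusted_rand_score(labels, member["unit"].to_numpy()))

        sig = [tuple(s) for s in manifest["stages"]["atlas"]["significant"]]
        atlas_unique = (len(sig) == 1
                        and (str(sig[0][0]), int(sig[0][1]))
                        == (str(gt["atlas_block"][0]), int(gt["atlas_block"][1])))

        takeover = manifest["stages"]["mirna"]["takeover_candidates"]
        takeover_exact = sorted(takeover) == sorted(gt["takeover_mirnas"])
        return {
            "target_precision": precision,
            "target_recall": recall,
            "diff_link_recall": diff_recall,
            "som_ari": ari,
            "atlas_unique_correct_call": bool(atlas_unique),
            "takeover_exact": bool(takeover_exact),
            "n_high_confidence": len(hc),
            "n_planted_targets": len(tgt),
            "n_planted_diff_links": len(diff),
            "n_som_tfs": len(member),
        }
    finally:
        if tmp is not None:
            tmp.cleanup()


# ---------------------------------------------------------------------------
# 6. statistical plumbing


def bh_oracle_check():
    """BH vs the literal step-up definition over all 2^10 two-level patterns."""
    import itertools

    def stepup(pvals):
        n = len(pvals)
        order = sorted(range(n), key=lambda i: pvals[i])
        adj = [0.0] * n
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, n * pvals[i] / rank)
            adj[i] = running
        return adj

    worst = 0.0
    n_patterns = 0
    for bits in itertools.product([0.013, 0.71], repeat=10):
        got = targets.bh_adjust(bits)
        expected = stepup(list(bits))
        worst = max(worst, float(np.abs(got - np.asarray(expected)).max()))
        n_patterns += 1
    return {"max_abs_diff": worst, "n_patterns": n_patterns}


def pearson_affine_invariance_check(n_trials=200, seed=3):
    """Pearson r unchanged (to 1e-12) under affine transforms."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        a, b = rng.uniform(0.1, 5.0), rng.uniform(-10, 10)
        r1 = stats.pearsonr(x, y).statistic
        r2 = stats.pearsonr(x, a * y + b).statistic
        worst = max(worst, abs(r1 - r2))
    return {"max_abs_diff": float(worst), "n_trials": n_trials}
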