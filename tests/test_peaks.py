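"""Recursive summit splitter, replicate consensus and 3'UTR signal tests.

The splitter is checked against an independently written brute-force
recursive oracle on random tracks, plus the analytic two-bump and boundary
cases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ripnet.containers import BindingSite, PileupTrack
from ripnet.peaks import (SiteParams, annotate_and_normalize, condition_specific_sites,
                          consensus_sites, recompute_depth_sums, split_sites)
from tests.conftest import make_expr


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain python, no shared helpers)

def oracle_split(depth, tau=10.0, f_primary=0.20, f_sub=0.05):
    """Reference splitter: returns (start, end, summit_height) triples."""
    depth = list(map(float, depth))

    def runs(lo, hi, thr):
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

    def recurse(lo, hi):
        s = max(depth[lo:hi])
        pieces = runs(lo, hi, f_sub * s)
        if pieces == [(lo, hi)]:
            return [(lo, hi, s)]
        sites = []
        for a, b in pieces:
            if max(depth[a:b]) >= tau:
                sites.extend(recurse(a, b))
        return sites

    sites = []
    for lo, hi in runs(0, len(depth), 1e-12):
        s = max(depth[lo:hi])
        if s < tau:
            continue
        for a, b in runs(lo, hi, f_primary * s):
            if max(depth[a:b]) >= max(f_primary * s, tau):
                sites.extend(recurse(a, b))
    return sorted(sites)


def random_track(rng, length=None):
    length = length or rng.integers(10, 500)
    kind = rng.integers(3)
    if kind == 0:
        depth = rng.poisson(rng.uniform(0.2, 6.0), length)
    elif kind == 1:
        depth = rng.integers(0, 100, length)
    else:  # spiky: sparse bumps over near-zero background
        depth = rng.poisson(0.3, length)
        for _ in range(rng.integers(1, 6)):
            c = rng.integers(0, length)
            w = int(rng.integers(3, 40))
            h = rng.uniform(5, 100)
            for i in range(max(0, c - w), min(length, c + w + 1)):
                depth[i] += int(h * max(0.0, 1 - abs(i - c) / (w + 1)))
    return PileupTrack("chr", 0, length, depth.astype(int))


def as_triples(sites):
    return sorted((int(s.start), int(s.end), float(s.summit_height)) for s in sites)


# ---------------------------------------------------------------------------


def test_splitter_matches_bruteforce_oracle_on_random_tracks():
    rng = np.random.default_rng(11)
    for _ in range(300):
        track = random_track(rng)
        got = as_triples(split_sites(track))
        expected = sorted(oracle_split(track.depth))
        assert got == expected


def test_all_zero_and_empty_tracks_yield_no_sites():
    assert split_sites(PileupTrack("r", 0, 50, np.zeros(50, int))) == []
    assert split_sites(PileupTrack("r", 0, 0, np.zeros(0, int))) == []


def test_plateau_below_background_threshold_is_discarded():
    depth = np.zeros(40, int)
    depth[10:30] = 9
    assert split_sites(PileupTrack("r", 0, 40, depth)) == []
    depth[10:30] = 10
    sites = split_sites(PileupTrack("r", 0, 40, depth))
    assert len(sites) == 1 and sites[0].summit_height == 10


def test_two_bumps_with_deep_valley_split_into_two_sites():
    # summit 40 at pos 10, summit 30 at pos 25, valley depth 3 < 0.2*40
    depth = np.zeros(40, int)
    for i in range(40):
        depth[i] = max(0, 40 - 4 * abs(i - 10))
        depth[i] = max(depth[i], 30 - 4 * abs(i - 25))
    depth[(depth > 0) & (depth < 4)] = 3
    sites = split_sites(PileupTrack("r", 0, 40, depth))
    assert [s.summit_height for s in sites] == [40, 30]
    assert sites[0].summit_pos == 10 and sites[1].summit_pos == 25


def test_summits_never_below_tau_and_monotone_in_tau():
    rng = np.random.default_rng(5)
    for _ in range(50):
        track = random_track(rng, length=200)
        n_prev = None
        for tau in (5, 10, 20, 40):
            sites = split_sites(track, SiteParams(tau_background=tau))
            assert all(s.summit_height >= tau for s in sites)
            if n_prev is not None:
                assert len(sites) <= n_prev
            n_prev = len(sites)


def test_resplitting_an_emitted_site_returns_it_unchanged():
    rng = np.random.default_rng(17)
    checked = 0
    for _ in range(80):
        track = random_track(rng, length=300)
        for s in split_sites(track):
            sub = PileupTrack("chr", 0, s.end - s.start,
                             np.asarray(track.depth[s.start:s.end]))
            again = split_sites(sub)
            assert len(again) == 1
            assert (again[0].start, again[0].end) == (0, s.end - s.start)
            assert again[0].summit_height == s.summit_height
            checked += 1
    assert checked > 50


def test_param_validation():
    with pytest.raises(ValueError):
        SiteParams(f_primary=0.05, f_sub=0.2)
    with pytest.raises(ValueError):
        SiteParams(tau_background=0)


# ---------------------------------------------------------------------------
# consensus / condition specificity


def _site(rid, a, b, h=20.0):
    return BindingSite(rid, a, b, (a + b) // 2, h)


def test_consensus_single_replicate_is_identity():
    sites = [_site("r", 0, 10), _site("r", 20, 30)]
    assert consensus_sites([sites]) == sites


def test_site_missing_from_one_replicate_is_dropped():
    rep1 = [_site("r", 0, 10), _site("r", 50, 60)]
    rep2 = [_site("r", 5, 12), _site("r", 52, 58)]
    rep3 = [_site("r", 8, 15)]  # second site absent
    out = consensus_sites([rep1, rep2, rep3])
    assert as_triples(out) == as_triples([rep1[0]])


def test_condition_specific_sites_set_algebra():
    wt = [_site("r", 0, 10), _site("r", 50, 60)]
    assert condition_specific_sites(wt, wt) == []
    ko = [_site("r", 100, 110)]
    assert condition_specific_sites(wt, ko) == wt
    assert condition_specific_sites(wt, [_site("r", 9, 20)]) == [wt[1]]


def test_consensus_recovers_planted_sites(pileup_data):
    tracks, gt = pileup_data
    cons = {}
    for cond in ("WT", "KO"):
        per_rep = [[s for t in tracks[cond][r] for s in split_sites(t)]
                   for r in sorted(tracks[cond])]
        cons[cond] = consensus_sites(per_rep)
    hits = 0
    for p in gt.planted_sites:
        conds = ("WT",) if p["specificity"] == "WT" else ("WT", "KO")
        if all(any(s.region_id == p["region_id"] and s.start < p["end"]
                   and p["start"] < s.end for s in cons[c]) for c in conds):
            hits += 1
    assert hits / len(gt.planted_sites) >= 0.95

    specific = condition_specific_sites(cons["WT"], cons["KO"])
    planted_wt = [p for p in gt.planted_sites if p["specificity"] == "WT"]
    rec = sum(any(s.region_id == p["region_id"] and s.start < p["end"]
                  and p["start"] < s.end for s in specific) for p in planted_wt)
    assert rec == len(planted_wt)
    # shared sites must not appear among WT-specific calls
    shared_regions = {p["region_id"] for p in gt.planted_sites
                      if p["specificity"] == "both"}
    assert not any(s.region_id in shared_regions and s.summit_height > 15
                   for s in specific)


# ---------------------------------------------------------------------------
# annotation & normalisation


def _annotation(rows):
    return pd.DataFrame(rows, columns=["region_id", "start", "end", "feature", "gene_id"])


def test_no_site_in_any_utr_yields_empty():
    ann = _annotation([("r", 100, 200, "three_prime_UTR", "g1")])
    expr = make_expr(np.full((1, 3), 10.0), ["g1"])
    assert annotate_and_normalize([_site("r", 0, 10)], ann, expr, "A") == []


def test_signal_normalisation_arithmetic():
    ann = _annotation([("r", 0, 50, "three_prime_UTR", "g1")])
    expr = make_expr(np.full((1, 3), 10.0), ["g1"])
    site = BindingSite("r", 5, 20, 10, 40.0, depth_sum=200.0)
    out = annotate_and_normalize([site], ann, expr, "A")
    assert len(out) == 1
    assert out[0].normalized_signal == pytest.approx(20.0)


def test_zero_expression_gene_reported_undefined():
    ann = _annotation([("r", 0, 50, "three_prime_UTR", "g1")])
    expr = make_expr(np.zeros((1, 3)), ["g1"])
    site = BindingSite("r", 5, 20, 10, 40.0, depth_sum=200.0)
    with pytest.warns(UserWarning):
        out = annotate_and_normalize([site], ann, expr, "A")
    assert out[0].normalized_signal is None


def test_malformed_annotation_raises():
    ann = _annotation([("r", 60, 50, "three_prime_UTR", "g1")])
    expr = make_expr(np.full((1, 3), 10.0), ["g1"])
    with pytest.raises(ValueError):
        annotate_and_normalize([_site("r", 0, 10)], ann, expr, "A")


def test_depth_sum_uses_replicate_mean():
    t1 = PileupTrack("r", 0, 10, np.full(10, 4))
    t2 = PileupTrack("r", 0, 10, np.full(10, 8))
    site = _site("r", 0, 10)
    out = recompute_depth_sums([site], [[t1], [t2]])
    assert out[0].depth_sum == pytest.approx(60.0)  # mean depth 6 x 10 bases
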