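"""AGO2-RIP binding-site definition by recursive summit splitting.

A binding site is a contiguous stretch of read pileup.  Candidate regions
(maximal runs of nonzero depth) are discarded outright when their summit is
below a background threshold (default 10 reads).  Surviving regions are cut
wherever the depth drops strictly below 20% of the region summit; each
emerging sub-site whose own summit clears both the 20% cutoff and the
background threshold is then recursively split at 5% of its *own* summit,
which keeps weak shoulders attached to their site.  Consensus across
replicates requires a site to overlap at least one site in every replicate;
condition-specific sites are consensus sites of one condition with no
overlap in the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ripnet.containers import BindingSite, ExpressionMatrix, PileupTrack


@dataclass
class SiteParams:
    """Thresholds of the splitter.

    tau_background: summit floor in reads; regions below it are background.
    f_primary: first-pass cut as a fraction of the region summit.
    f_sub: recursive cut as a fraction of each sub-site's own summit.
    """

    tau_background: float = 10.0
    f_primary: float = 0.20
    f_sub: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.f_sub < self.f_primary < 1.0):
            raise ValueError("need 0 < f_sub < f_primary < 1")
        if self.tau_background < 1:
            raise ValueError("tau_background must be >= 1")


def _runs_at_least(depth: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Maximal [start, end) runs with depth >= thr (ties kept inside sites)."""
    keep = depth >= thr
    if not keep.any():
        return []
    padded = np.concatenate(([False], keep, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _summit(depth: np.ndarray, lo: int, hi: int) -> tuple[int, float]:
    """Leftmost position of the maximum in [lo, hi)."""
    seg = depth[lo:hi]
    pos = int(np.argmax(seg))
    return lo + pos, float(seg[pos])


def split_sites(track: PileupTrack, params: SiteParams | None = None) -> list[BindingSite]:
    """Split one pileup track into binding sites.

    Returns disjoint sites ordered by start; every summit is at least
    ``params.tau_background``.  An empty or all-zero track yields an empty
    list.
    """
    params = params or SiteParams()
    depth = np.asarray(track.depth, dtype=float)
    sites: list[BindingSite] = []
    for ci, (lo, hi) in enumerate(_runs_at_least(depth, 1e-12)):  # depth > 0 runs
        parent = f"{track.region_id}:cand{ci}"
        sites.extend(_split_candidate(depth, lo, hi, params, track, parent))
    sites.sort(key=lambda s: s.start)
    return sites


def _split_candidate(depth, lo, hi, params: SiteParams, track, parent) -> list[BindingSite]:
    _, s = _summit(depth, lo, hi)
    if s < params.tau_background:
        return []
    thr = params.f_primary * s
    eligible = max(params.f_primary * s, params.tau_background)
    out = []
    for a, b in _runs_at_least(depth[lo:hi], thr):
        _, ss = _summit(depth, lo + a, lo + b)
        if ss >= eligible:
            out.extend(_split_sub(depth, lo + a, lo + b, params, track, parent))
    return out


def _split_sub(depth, lo, hi, params: SiteParams, track, parent) -> list[BindingSite]:
    """Recursive 5%-of-own-summit splitting; emits maximal uncut stretches."""
    pos, ss = _summit(depth, lo, hi)
    runs = _runs_at_least(depth[lo:hi], params.f_sub * ss)
    if len(runs) == 1 and runs[0] == (0, hi - lo):
        return [BindingSite(track.region_id, lo, hi, pos, ss, parent,
                            depth_sum=float(depth[lo:hi].sum()))]
    out = []
    for a, b in runs:
        _, sub_s = _summit(depth, lo + a, lo + b)
        if sub_s >= params.tau_background:
            out.extend(_split_sub(depth, lo + a, lo + b, params, track, parent))
    return out


# ---------------------------------------------------------------------------
# consensus & condition specificity


def _overlaps_any(site: BindingSite, others: Sequence[BindingSite]) -> bool:
    return any(site.overlaps(o) for o in others)


def consensus_sites(per_replicate_sites: Sequence[Sequence[BindingSite]]) -> list[BindingSite]:
    """Sites of replicate 1 that overlap >= 1 site in every other replicate.

    Overlap means at least one shared base on the same region.
    """
    if len(per_replicate_sites) == 0:
        raise ValueError("need at least one replicate")
    first, *rest = per_replicate_sites
    out = []
    for site in first:
        if all(_overlaps_any(site, rep) for rep in rest):
            out.append(site)
    return out


def condition_specific_sites(wt_sites: Sequence[BindingSite],
                             ko_sites: Sequence[BindingSite]) -> list[BindingSite]:
    """WT consensus sites with no overlapping KO consensus site."""
    return [s for s in wt_sites if not _overlaps_any(s, ko_sites)]


# ---------------------------------------------------------------------------
# annotation & whole-cell normalisation


@dataclass
class GeneSignal:
    """Summed 3'UTR IP signal for one gene, normalised by whole-cell expression."""

    gene_id: str
    utr3_ip_signal: float
    wholecell_expr: float
    normalized_signal: float | None  # None when the gene is not expressed


def recompute_depth_sums(sites: Sequence[BindingSite],
                         replicate_tracks: Sequence[Sequence[PileupTrack]]) -> list[BindingSite]:
    """Replace each site's depth_sum with the replicate-mean depth sum.

    ``replicate_tracks`` holds the same-condition tracks, one list per
    replicate; signal comparisons between conditions are made on replicate
    means.
    """
    by_region: dict[str, list[np.ndarray]] = {}
    for rep in replicate_tracks:
        for t in rep:
            by_region.setdefault(t.region_id, []).append(np.asarray(t.depth, float))
    out = []
    for s in sites:
        mean_depth = np.mean(by_region[s.region_id], axis=0)
        out.append(BindingSite(s.region_id, s.start, s.end, s.summit_pos,
                               s.summit_height, s.parent_id,
                               depth_sum=float(mean_depth[s.start:s.end].sum())))
    return out


def annotate_and_normalize(sites: Sequence[BindingSite],
                           annotation: pd.DataFrame,
                           expr: ExpressionMatrix,
                           condition: str = "WT",
                           timepoint: int | None = None) -> list[GeneSignal]:
    """Sum site signal inside annotated 3'UTRs and normalise by expression.

    ``annotation`` needs columns region_id, start, end, feature, gene_id
    (0-based half-open); only ``three_prime_UTR`` rows are used.  Each gene's
    summed overlapping ``depth_sum`` is divided by its mean whole-cell
    expression in the matching condition (optionally one timepoint).  Genes
    without expression are reported with ``normalized_signal=None`` and are
    excluded downstream.
    """
    utr = annotation[annotation["feature"] == "three_prime_UTR"]
    if (utr["start"] < 0).any() or (utr["start"] >= utr["end"]).any():
        raise ValueError("malformed annotation intervals (expected 0-based half-open)")
    expr_sub = expr.subset(condition=condition, timepoint=timepoint)
    mean_expr = expr_sub.values.mean(axis=1)

    ip_sum: dict[str, float] = {}
    for _, row in utr.iterrows():
        for s in sites:
            if (s.region_id == row.region_id and s.start < row.end
                    and row.start < s.end):
                ip_sum[row.gene_id] = ip_sum.get(row.gene_id, 0.0) + s.depth_sum
    out = []
    for gid, sig in sorted(ip_sum.items()):
        wce = float(mean_expr.get(gid, 0.0))
        norm = sig / wce if wce > 0 else None
        if norm is None:
            warnings.warn(f"gene {gid} has 3'UTR IP signal but no whole-cell "
                          "expression; normalized signal undefined")
        out.append(GeneSignal(gid, sig, wce, norm))
    return out


def gene_signal_table(signals: Sequence[GeneSignal]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.gene_id, g.utr3_ip_signal, g.wholecell_expr, g.normalized_signal)
         for g in signals],
        columns=["gene_id", "utr3_ip_signal", "wholecell_expr", "normalized_signal"],
    )
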