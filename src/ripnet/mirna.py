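"""nCounter-style miRNA normalisation, abundance filtering, takeover
detection and AGO2 activity ranking.

Raw counts are normalised per replicate to that sample's housekeeping mean,
making the values invariant to lane depth.  Candidate "takeover" miRNAs —
species picking up regulatory load after the dominant miRNA is ablated —
are the three-way intersection of miRNAs up-regulated in the knockout AGO2
IP, up-regulated in knockout whole-cell counts, and abundant (raw counts
above a threshold in at least one sample).  Activity within the RISC is the
IP/whole-cell signal ratio, ranked within each condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ripnet.containers import ExpressionMatrix


def normalize_counts(table: pd.DataFrame, housekeeping: Sequence[str]) -> pd.DataFrame:
    """Divide each sample's counts by that sample's housekeeping mean."""
    hk = [h for h in housekeeping if h in table.index]
    if not hk:
        raise ValueError("housekeeping set is empty or absent from the table")
    factors = table.loc[hk].mean(axis=0)
    if (factors <= 0).any():
        raise ValueError("a sample has zero housekeeping counts")
    return table / factors


def replicate_means(norm: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Mean normalised counts per (condition, timepoint) group."""
    groups = sample_meta.groupby(["condition", "timepoint"]).groups
    out = {key: norm[list(cols)].mean(axis=1) for key, cols in groups.items()}
    means = pd.DataFrame(out)
    means.columns = pd.MultiIndex.from_tuples(means.columns,
                                              names=["condition", "timepoint"])
    return means


def filter_abundant(table: pd.DataFrame, min_counts: float = 200.0,
                    exclude: Iterable[str] = ()) -> list[str]:
    """miRNAs with raw counts strictly above ``min_counts`` in >= 1 sample."""
    excl = set(exclude)
    mask = (table > min_counts).any(axis=1)
    return [m for m in table.index[mask] if m not in excl]


def takeover_candidates(ip_de: pd.DataFrame, wholecell_de: pd.DataFrame,
                        abundant_ids: Iterable[str],
                        alpha: float = 0.05) -> list[str]:
    """Abundant miRNAs up-regulated in the knockout in both IP and whole cell.

    DE tables use the standard schema (gene_id, log2fc, pvalue, padj) on the
    knockout-versus-WT contrast.
    """
    def up(de: pd.DataFrame) -> set[str]:
        return set(de.loc[(de["log2fc"] > 0) & (de["padj"] < alpha), "gene_id"])

    return sorted(up(ip_de) & up(wholecell_de) & set(abundant_ids))


@dataclass
class ActivityRank:
    mirna: str
    condition: str
    ip_signal: float
    wholecell_signal: float
    activity: float
    rank: int


def activity_rank(ip_signal: pd.DataFrame,
                  wholecell_signal: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank miRNAs by IP/whole-cell activity within each condition.

    Inputs are miRNA x condition signal tables (e.g. replicate-mean
    normalised counts at one timepoint).  miRNAs with zero whole-cell signal
    in a condition are excluded from that condition with a warning.  Returns
    (rank table, rank-shift table); ranks are 1 = highest activity, unique
    within condition (ties broken by miRNA id), and the shift is
    rank_first_condition - rank_second_condition over shared miRNAs.
    """
    conditions = list(ip_signal.columns)
    rows = []
    for cond in conditions:
        ip = ip_signal[cond]
        wc = wholecell_signal[cond]
        zero = wc.index[wc == 0]
        if len(zero):
            warnings.warn(f"{len(zero)} miRNA(s) with zero whole-cell signal "
                          f"excluded from {cond} activity ranking")
        valid = wc.index.difference(zero)
        act = (ip.loc[valid] / wc.loc[valid])
        order = act.to_frame("activity").reset_index(names="mirna")
        order = order.sort_values(["activity", "mirna"],
                                  ascending=[False, True], kind="mergesort")
        order["rank"] = np.arange(1, len(order) + 1)
        for _, r in order.iterrows():
            rows.append((r["mirna"], cond, float(ip.loc[r["mirna"]]),
                         float(wc.loc[r["mirna"]]), float(r["activity"]),
                         int(r["rank"])))
    ranks = pd.DataFrame(rows, columns=["mirna", "condition", "ip_signal",
                                        "wholecell_signal", "activity", "rank"])
    shifts = pd.DataFrame()
    if len(conditions) == 2:
        a, b = conditions
        ra = ranks[ranks["condition"] == a].set_index("mirna")["rank"]
        rb = ranks[ranks["condition"] == b].set_index("mirna")["rank"]
        shared = ra.index.intersection(rb.index)
        shifts = pd.DataFrame({
            "mirna": shared,
            f"rank_{a}": ra.loc[shared].to_numpy(),
            f"rank_{b}": rb.loc[shared].to_numpy(),
            "rank_shift": (ra.loc[shared] - rb.loc[shared]).to_numpy(),
        })
    return ranks, shifts


def density_summary(norm: pd.DataFrame, sample_meta: pd.DataFrame,
                    n_bins: int = 30) -> pd.DataFrame:
    """Per-condition histograms of log10 normalised counts (long format)."""
    logx = np.log10(norm.replace(0, np.nan)).stack().rename("log10_norm")
    meta = sample_meta.loc[logx.index.get_level_values(1)]
    df = pd.DataFrame({"log10_norm": logx.to_numpy(),
                       "condition": meta["condition"].to_numpy(),
                       "timepoint": meta["timepoint"].to_numpy()})
    lo, hi = df["log10_norm"].min(), df["log10_norm"].max()
    bins = np.linspace(lo, hi, n_bins + 1)
    rows = []
    for (cond, tp), sub in df.groupby(["condition", "timepoint"]):
        hist, _ = np.histogram(sub["log10_norm"], bins=bins, density=True)
        centres = (bins[:-1] + bins[1:]) / 2
        for c, h in zip(centres, hist):
            rows.append((cond, tp, float(c), float(h)))
    return pd.DataFrame(rows, columns=["condition", "timepoint", "bin_centre",
                                       "density"])
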