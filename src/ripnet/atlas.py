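"""Developmental-atlas correlation profiling.

Sample expression profiles (the top differentially expressed genes of a
timepoint versus day 0) are correlated against a region x age expression
atlas; a (region, age) match is called significant when its correlation
exceeds the mean of the other regions at the same age by more than twice the
standard deviation of correlations among similar-age samples (the age and
its immediate ordered neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ripnet.containers import ExpressionMatrix
from ripnet.targets import de_between_timepoints


def top_de_genes(expr: ExpressionMatrix, condition: str, timepoint: int,
                 reference_timepoint: int = 0, n_top: int = 1000,
                 de_table: pd.DataFrame | None = None) -> list[str]:
    """Top ``n_top`` genes by DE significance of a timepoint vs the reference.

    Ranked by padj ascending, ties broken by |log2fc| descending then gene
    id; an externally computed DE table in the standard schema may be passed
    instead of running the built-in test.
    """
    de = de_table if de_table is not None else de_between_timepoints(
        expr, condition, timepoint, reference_timepoint)
    de = de.assign(_absfc=de["log2fc"].abs())
    de = de.sort_values(["padj", "_absfc", "gene_id"],
                        ascending=[True, False, True], kind="mergesort")
    return de["gene_id"].head(n_top).tolist()


@dataclass
class CorrelationCall:
    region: str
    age: int
    r: float
    significant: bool = False


def correlate_to_atlas(profile: pd.Series, atlas: pd.DataFrame,
                       gene_set: Sequence[str] | None = None) -> list[CorrelationCall]:
    """Pearson r of a sample profile against every atlas (region, age) column.

    Both sides are log2(x+1)-transformed; the correlation runs over the
    intersection of ``gene_set`` (default: all shared genes) with both
    namespaces.
    """
    genes = pd.Index(gene_set) if gene_set is not None else profile.index
    shared = genes.intersection(profile.index).intersection(atlas.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes between profile and atlas")
    q = np.log2(profile.loc[shared].to_numpy(dtype=float) + 1.0)
    out = []
    for (region, age), col in atlas.items():
        a = np.log2(col.loc[shared].to_numpy(dtype=float) + 1.0)
        r = float(stats.pearsonr(q, a).statistic)
        out.append(CorrelationCall(str(region), int(age), r))
    return out


def call_region_age(calls: Sequence[CorrelationCall],
                    age_window: int = 1) -> list[CorrelationCall]:
    """Apply the two-SD significance rule to correlation calls.

    A (region, age) call is significant when its r exceeds the mean r of the
    *other* regions at the same age by more than twice the SD of r among
    similar-age samples — columns whose age index lies within
    ``age_window`` ordered steps of the call's age, the call itself
    excluded.
    """
    ages = sorted({c.age for c in calls})
    order = {a: i for i, a in enumerate(ages)}
    out = []
    for c in calls:
        same_age_others = [o.r for o in calls
                           if o.age == c.age and o is not c]
        pool = [o.r for o in calls
                if abs(order[o.age] - order[c.age]) <= age_window and o is not c]
        if not same_age_others:
            out.append(CorrelationCall(c.region, c.age, c.r, False))
            continue
        diff = c.r - float(np.mean(same_age_others))
        sd = float(np.std(pool, ddof=1)) if len(pool) > 1 else 0.0
        out.append(CorrelationCall(c.region, c.age, c.r, bool(diff > 2.0 * sd)))
    return out


def merge_regions(atlas: pd.DataFrame, regions_to_merge: Sequence[str],
                  merged_name: str | None = None) -> pd.DataFrame:
    """Average the named regions' columns at shared ages; union of ages.

    Ages covered by only one of the merged regions are carried through
    unchanged.  Other regions are untouched.
    """
    merged_name = merged_name or "+".join(regions_to_merge)
    keep = atlas.loc[:, ~atlas.columns.get_level_values("region").isin(regions_to_merge)]
    sub = atlas.loc[:, atlas.columns.get_level_values("region").isin(regions_to_merge)]
    if sub.shape[1] == 0:
        return atlas
    merged = sub.T.groupby(level="age").mean().T
    merged.columns = pd.MultiIndex.from_tuples(
        [(merged_name, a) for a in merged.columns], names=["region", "age"])
    out = pd.concat([keep, merged], axis=1)
    return out.sort_index(axis=1, level=["region", "age"])


def calls_table(calls: Sequence[CorrelationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.region, c.age, c.r, c.significant) for c in calls],
        columns=["region", "age", "r", "significant"],
    )
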