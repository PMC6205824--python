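"""High-confidence miRNA target filtering.

The target definition is the three-way intersection of (1) genes whose 3'UTR
AGO2 signal is specific to WT (lost in the knockout), (2) genes
significantly up-regulated in knockout whole-cell RNA, and (3) genes present
in an annotated-target list.  Differential expression is a pluggable stage:
the built-in default is a Welch two-sample test on log2(count+1) with
Benjamini-Hochberg adjustment, and externally computed tables in the same
schema plug in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ripnet.containers import ExpressionMatrix

DE_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj"]


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def welch_log2(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch test of log2-transformed groups; returns (log2fc b-a, p).

    Degenerate zero-variance groups get p=1 when the means agree and p=0
    otherwise.
    """
    fc = float(b.mean() - a.mean())
    if np.allclose(a.var(ddof=0), 0.0) and np.allclose(b.var(ddof=0), 0.0):
        return fc, (1.0 if np.isclose(fc, 0.0) else 0.0)
    p = stats.ttest_ind(b, a, equal_var=False).pvalue
    return fc, (1.0 if np.isnan(p) else float(p))


def de_test(expr: ExpressionMatrix,
            condition_pair: tuple[str, str] = ("WT", "KO"),
            timepoint: int | None = None) -> pd.DataFrame:
    """Per-gene differential expression between two conditions.

    log2 fold change is ``condition_pair[1]`` (e.g. knockout) versus
    ``condition_pair[0]``; p-values are BH-adjusted across genes.
    """
    ref, alt = condition_pair
    a = expr.subset(condition=ref, timepoint=timepoint).values
    b = expr.subset(condition=alt, timepoint=timepoint).values
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("de_test needs >= 2 replicates per condition")
    la = np.log2(a.to_numpy(dtype=float) + 1.0)
    lb = np.log2(b.to_numpy(dtype=float) + 1.0)
    rows = [welch_log2(la[i], lb[i]) for i in range(la.shape[0])]
    out = pd.DataFrame(rows, columns=["log2fc", "pvalue"])
    out.insert(0, "gene_id", expr.genes.to_numpy())
    out["padj"] = bh_adjust(out["pvalue"])
    return out


def de_between_timepoints(expr: ExpressionMatrix, condition: str,
                          timepoint: int, reference_timepoint: int = 0) -> pd.DataFrame:
    """DE of one condition's timepoint vs a reference timepoint (same schema)."""
    a = expr.subset(condition=condition, timepoint=reference_timepoint).values
    b = expr.subset(condition=condition, timepoint=timepoint).values
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("de_between_timepoints needs >= 2 replicates per group")
    la = np.log2(a.to_numpy(dtype=float) + 1.0)
    lb = np.log2(b.to_numpy(dtype=float) + 1.0)
    rows = [welch_log2(la[i], lb[i]) for i in range(la.shape[0])]
    out = pd.DataFrame(rows, columns=["log2fc", "pvalue"])
    out.insert(0, "gene_id", expr.genes.to_numpy())
    out["padj"] = bh_adjust(out["pvalue"])
    return out


@dataclass
class TargetCall:
    gene_id: str
    has_wt_specific_utr_site: bool
    upregulated_in_ko: bool
    annotated_target: bool

    @property
    def high_confidence(self) -> bool:
        return (self.has_wt_specific_utr_site and self.upregulated_in_ko
                and self.annotated_target)


def intersect_targets(wt_specific_genes: Iterable[str],
                      de: pd.DataFrame,
                      annotated: Iterable[str],
                      alpha: float = 0.05) -> list[TargetCall]:
    """Flag genes by the three criteria; returns genes with >= 1 flag set.

    ``wt_specific_genes`` are genes with WT-only consensus 3'UTR sites;
    ``de`` is a DE table (gene_id, log2fc, pvalue, padj) on the knockout
    versus WT contrast; ``annotated`` is the annotated-target list.
    Up-regulated means log2fc > 0 with padj < alpha.
    """
    if de["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in DE table")
    site_set = set(wt_specific_genes)
    ann_set = set(annotated)
    up_set = set(de.loc[(de["log2fc"] > 0) & (de["padj"] < alpha), "gene_id"])
    calls = []
    for gid in sorted(site_set | up_set | ann_set):
        calls.append(TargetCall(gid, gid in site_set, gid in up_set, gid in ann_set))
    return calls


def high_confidence_targets(calls: Sequence[TargetCall]) -> list[str]:
    return [c.gene_id for c in calls if c.high_confidence]


def venn_summary(calls: Sequence[TargetCall]) -> dict[str, int]:
    """Set sizes and all intersection cardinalities of the three criteria."""
    s = {c.gene_id for c in calls if c.has_wt_specific_utr_site}
    u = {c.gene_id for c in calls if c.upregulated_in_ko}
    a = {c.gene_id for c in calls if c.annotated_target}
    return {
        "wt_specific_site": len(s),
        "upregulated_in_ko": len(u),
        "annotated_target": len(a),
        "site_and_up": len(s & u),
        "site_and_annotated": len(s & a),
        "up_and_annotated": len(u & a),
        "high_confidence": len(s & u & a),
    }


def calls_table(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.has_wt_specific_utr_site, c.upregulated_in_ko,
          c.annotated_target, c.high_confidence) for c in calls],
        columns=["gene_id", "has_wt_specific_utr_site", "upregulated_in_ko",
                 "annotated_target", "high_confidence"],
    )
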