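"""Signed weighted topological overlap (wTO) networks with bootstrap link
probabilities.

For a node pair (i, j) drawn from a node set (here: transcription factors)
embedded in a background of all expressed genes, the signed wTO is

    omega_ij = ( sum_{u != i,j} a_iu * a_uj  +  a_ij )
               / ( min(k_i, k_j) + 1 - |a_ij| ),

where a_xy is the Pearson correlation between genes x and y across samples
and k_i = sum_{u != i} |a_iu| runs over every expressed gene.  Correcting a
pair by the whole expressed background suppresses spurious pairwise
correlations: a high |omega| needs the two nodes to agree with the rest of
the transcriptome, not just with each other.  |omega_ij| <= 1 always.

Link significance comes from resampling the sample columns with replacement:
the empirical two-sided probability that the resampled omega crosses zero,

    p = 2 * min(#{omega* <= 0}, #{omega* >= 0}) / B,

is the probability of the relationship being random; links above the cut
(default 0.10) are dropped from the reported network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ripnet.containers import ExpressionMatrix


@dataclass
class WTOParams:
    correlation: str = "pearson"
    n_bootstrap: int = 1000
    p_cut: float = 0.10
    rpkm_min: float = 5.0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not (0.0 < self.p_cut < 1.0):
            raise ValueError("p_cut must be in (0, 1)")
        if self.correlation != "pearson":
            raise ValueError("only Pearson correlation is supported")


def filter_expressed(expr: ExpressionMatrix, rpkm_min: float = 5.0) -> ExpressionMatrix:
    """Drop genes below the expression floor on *every* day.

    A gene survives if its replicate-mean RPKM reaches ``rpkm_min`` in at
    least one condition/timepoint group (a gene is removed only if it is
    below the floor for each day).
    """
    groups = expr.samples.groupby(["condition", "timepoint"]).groups
    keep = pd.Series(False, index=expr.genes)
    for cols in groups.values():
        keep |= expr.values[list(cols)].mean(axis=1) >= rpkm_min
    return ExpressionMatrix(expr.values.loc[keep], expr.samples)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Rows centred and scaled so that z @ z.T is the Pearson matrix.

    Zero-variance rows become all-zero (correlations 0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0.0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s); "
                      "their correlations are set to 0")
    sd[flat] = 1.0
    z = (x - mu) / (sd * np.sqrt(x.shape[1]))
    z[flat] = 0.0
    return z


def wto_from_correlation(corr: np.ndarray, node_idx: Sequence[int]) -> np.ndarray:
    """Signed wTO for node pairs given a full gene-gene correlation matrix.

    ``corr`` is G x G with unit diagonal; returns the n_nodes x n_nodes
    omega matrix (zero diagonal).  Useful for checking the formula against
    hand-evaluated correlation structures.
    """
    corr = np.asarray(corr, dtype=float)
    node_idx = np.asarray(node_idx)
    m = corr[node_idx]                        # node-vs-all
    a = m[:, node_idx]
    k = np.abs(m).sum(axis=1) - np.abs(m[np.arange(len(node_idx)), node_idx])
    num = m @ corr[:, node_idx] - a           # = sum_{u!=i,j} a_iu a_uj + a_ij
    denom = np.minimum.outer(k, k) + 1.0 - np.abs(a)
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = num / denom
    omega[denom == 0.0] = 0.0
    np.fill_diagonal(omega, 0.0)
    return omega


def _wto_matrix(x: np.ndarray, node_idx: np.ndarray) -> np.ndarray:
    """Signed wTO for all node pairs given genes x samples data ``x``."""
    z = _standardize_rows(x)
    zn = z[node_idx]
    m = zn @ z.T                      # node-vs-all Pearson (n_nodes x G)
    m = np.clip(m, -1.0, 1.0)
    a = m[:, node_idx]                # node-vs-node correlations
    k = np.abs(m).sum(axis=1) - np.abs(m[np.arange(len(node_idx)), node_idx])
    # numerator: sum_u m_iu m_ju over all u, minus the u=i and u=j terms,
    # plus a_ij back  ->  (M M^T)_ij - a_ij  (using m_ii = 1)
    num = m @ m.T - a
    denom = np.minimum.outer(k, k) + 1.0 - np.abs(a)
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = num / denom
    omega[denom == 0.0] = 0.0
    np.fill_diagonal(omega, 0.0)
    return omega


def _node_indices(genes: pd.Index, node_set: Sequence[str]) -> np.ndarray:
    missing = [n for n in node_set if n not in genes]
    if missing:
        raise ValueError(f"node(s) not in expressed genes: {missing[:5]}")
    lookup = {g: i for i, g in enumerate(genes)}
    return np.array([lookup[n] for n in node_set])


def _links_frame(node_set: Sequence[str], omega: np.ndarray,
                 pval: np.ndarray | None = None) -> pd.DataFrame:
    iu = np.triu_indices(len(node_set), k=1)
    out = pd.DataFrame({
        "node_i": np.asarray(node_set)[iu[0]],
        "node_j": np.asarray(node_set)[iu[1]],
        "omega": omega[iu],
    })
    if pval is not None:
        out["pval"] = pval[iu]
    return out


def wto(expr: ExpressionMatrix, node_set: Sequence[str],
        params: WTOParams | None = None) -> pd.DataFrame:
    """Signed wTO links for every node pair, corrected by all expressed genes.

    Returns an edge list (node_i, node_j, omega) over the upper triangle.
    """
    params = params or WTOParams()
    if expr.values.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    idx = _node_indices(expr.genes, node_set)
    omega = _wto_matrix(expr.values.to_numpy(), idx)
    return _links_frame(node_set, omega)


def wto_bootstrap(expr: ExpressionMatrix, node_set: Sequence[str],
                  params: WTOParams | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """wTO links with bootstrap zero-crossing probabilities.

    Sample columns are resampled with replacement within each
    condition/timepoint group, ``params.n_bootstrap`` times.  Returns the
    full edge list with a ``pval`` column; use :func:`significant_links` to
    apply the probability cut.
    """
    params = params or WTOParams()
    x = expr.values.to_numpy()
    if x.shape[1] < 4:
        raise ValueError("need >= 4 samples for the bootstrap")
    idx = _node_indices(expr.genes, node_set)
    omega = _wto_matrix(x, idx)

    groups = [np.asarray(cols) for cols in
              expr.samples.reset_index().groupby(
                  ["condition", "timepoint"]).indices.values()]
    rng = np.random.default_rng(seed)
    n = len(node_set)
    le = np.zeros((n, n))
    ge = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # resamples may hit zero variance
        for _ in range(params.n_bootstrap):
            cols = np.concatenate([rng.choice(g, size=len(g), replace=True)
                                   for g in groups])
            ob = _wto_matrix(x[:, cols], idx)
            le += ob <= 0.0
            ge += ob >= 0.0
    pval = np.minimum(2.0 * np.minimum(le, ge) / params.n_bootstrap, 1.0)
    return _links_frame(node_set, omega, pval)


def significant_links(links: pd.DataFrame, p_cut: float = 0.10) -> pd.DataFrame:
    """Links retained at the bootstrap probability cut (pval <= p_cut)."""
    return links[links["pval"] <= p_cut].reset_index(drop=True)
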