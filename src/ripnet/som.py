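"""Self-organizing-map clustering of fold-change trajectories.

TFs that are differentially expressed on every day of the 1..4 window are
clustered by their normalized fold-change (nFC) pattern: the per-day log2
fold change, standardised across TFs day by day.  A batch SOM on a
rectangular grid with a Gaussian neighborhood is grown (1x2, 1x3, 2x2, ...)
until the average distortion (mean squared member-to-prototype distance)
falls under a cut, and cluster trajectories are summarised with a local
(loess-style) regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator


def persistent_de_tfs(de_per_day: Mapping[int, pd.DataFrame],
                      tf_list: Sequence[str],
                      alpha: float = 0.05) -> pd.DataFrame:
    """TFs significant on every listed day, with their nFC trajectories.

    ``de_per_day`` maps day -> DE table (gene_id, log2fc, pvalue, padj).
    Returns a TFs x days DataFrame of per-day log2 fold changes standardised
    across the selected TFs (z-score per day).  Empty when no TF is
    persistently significant.
    """
    days = sorted(de_per_day)
    tf_set = set(tf_list)
    persistent: set[str] | None = None
    for d in days:
        tab = de_per_day[d]
        sig = set(tab.loc[tab["padj"] < alpha, "gene_id"]) & tf_set
        persistent = sig if persistent is None else persistent & sig
    persistent = sorted(persistent or [])
    if not persistent:
        return pd.DataFrame(columns=days)
    mat = pd.DataFrame(index=persistent, columns=days, dtype=float)
    for d in days:
        fc = de_per_day[d].set_index("gene_id")["log2fc"]
        mat[d] = fc.reindex(persistent)
    sd = mat.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (mat - mat.mean(axis=0)) / sd


def _grid_sequence(max_units: int):
    """Most-square (rows, cols) grids by increasing unit count: 1x2, 1x3, 2x2..."""
    for n in range(2, max_units + 1):
        r = max(d for d in range(1, int(np.sqrt(n)) + 1) if n % d == 0)
        yield r, n // r


@dataclass
class SOMFit:
    grid: tuple[int, int]
    codebook: np.ndarray                  # n_units x n_days
    membership: pd.Series                 # TF -> unit index
    qerror_per_unit: np.ndarray           # mean member distance per unit
    avg_distortion: float                 # mean squared member distance
    path: list = field(default_factory=list)  # (grid, distortion) growth path

    @property
    def n_units(self) -> int:
        return self.grid[0] * self.grid[1]


def _train_som(x: np.ndarray, grid: tuple[int, int], seed: int,
               n_epochs: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Batch SOM; returns (codebook, bmu assignment).

    Gaussian neighborhood with radius decaying linearly from half the larger
    grid dimension to 0.3, so late epochs are essentially Lloyd updates.
    """
    rows, cols = grid
    n_units = rows * cols
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    # linear (principal-axis) initialisation: spread the codebook along the
    # first two principal components, avoiding dead units on small grids
    centred = x - x.mean(axis=0)
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    sd = svals / np.sqrt(max(len(x) - 1, 1))
    axes = np.zeros((2, x.shape[1]))
    axes[0] = vt[0] * sd[0]
    if len(sd) > 1 and rows > 1 and cols > 1:
        axes[1] = vt[1] * sd[1]
    long_is_cols = cols >= rows
    pos = np.empty((n_units, 2))
    for u, (r, c) in enumerate(coords):
        main, side = (c, r) if long_is_cols else (r, c)
        n_main, n_side = (cols, rows) if long_is_cols else (rows, cols)
        pos[u, 0] = 0.0 if n_main == 1 else 2.0 * (main / (n_main - 1) - 0.5)
        pos[u, 1] = 0.0 if n_side == 1 else 2.0 * (side / (n_side - 1) - 0.5)
    codebook = x.mean(axis=0) + 1.5 * pos @ axes
    rng = np.random.default_rng(seed)
    codebook = codebook + rng.normal(0, 1e-9, codebook.shape)  # tie-break only

    r0, r1 = max(rows, cols) / 2.0, 0.3
    for epoch in range(n_epochs):
        radius = r0 + (r1 - r0) * epoch / max(n_epochs - 1, 1)
        d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
        bmu = d2.argmin(axis=1)
        h = np.exp(-grid_d2[:, bmu] / (2.0 * radius ** 2))  # units x samples
        denom = h.sum(axis=1, keepdims=True)
        denom[denom == 0.0] = 1.0
        codebook = (h @ x) / denom
    d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    return codebook, d2.argmin(axis=1)


def _lloyd_refine(x: np.ndarray, codebook: np.ndarray,
                  n_iter: int = 15) -> np.ndarray:
    """Nearest-prototype mean updates; never increases the distortion."""
    codebook = codebook.copy()
    for _ in range(n_iter):
        d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
        bmu = d2.argmin(axis=1)
        for u in range(len(codebook)):
            members = x[bmu == u]
            if len(members):
                codebook[u] = members.mean(axis=0)
    return codebook


def _grow_codebook(x: np.ndarray, prev: np.ndarray, n_units: int) -> np.ndarray:
    """Warm-start a larger codebook: keep the previous prototypes and place
    the extra units at the worst-fitted trajectories."""
    d2 = ((x[:, None, :] - prev[None, :, :]) ** 2).sum(-1).min(axis=1)
    extra = x[np.argsort(d2)[::-1][: n_units - len(prev)]]
    return np.vstack([prev, extra])


def fit_som(nfc: pd.DataFrame, seed: int = 0,
            distortion_cut: float = 10.0) -> SOMFit:
    """Grow the SOM grid until the average distortion falls below the cut.

    Returns the first grid along the growth path (1x2, 1x3, 2x2, ...) whose
    mean squared member-to-prototype distance is under ``distortion_cut``.
    Each larger grid is trained both fresh (batch SOM) and warm-started from
    the previous codebook plus the worst-fitted trajectories, and the better
    of the two is kept, so the distortion is non-increasing along the growth
    path.  If the cut is unreachable by the time the grid matches the sample
    count, the finest grid is returned with a warning.
    """
    if len(nfc) < 2:
        raise ValueError("need at least two trajectories")
    x = nfc.to_numpy(dtype=float)
    best: SOMFit | None = None
    path: list = []
    prev_codebook: np.ndarray | None = None
    for grid in _grid_sequence(len(nfc)):
        n_units = grid[0] * grid[1]
        codebook, _ = _train_som(x, grid, seed)
        if prev_codebook is not None:
            warm = _lloyd_refine(x, _grow_codebook(x, prev_codebook, n_units))
            def _dist(cb):
                return float(((x - cb[((x[:, None, :] - cb[None, :, :]) ** 2)
                                      .sum(-1).argmin(axis=1)]) ** 2)
                             .sum(axis=1).mean())
            if _dist(warm) < _dist(codebook):
                codebook = warm
        sq_all = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
        bmu = sq_all.argmin(axis=1)
        sq = sq_all[np.arange(len(x)), bmu]
        qerr = np.zeros(n_units)
        for u in range(n_units):
            members = sq[bmu == u]
            qerr[u] = float(np.sqrt(members).mean()) if len(members) else 0.0
        path.append((grid, float(sq.mean())))
        fit = SOMFit(grid, codebook,
                     pd.Series(bmu, index=nfc.index, name="unit"),
                     qerr, float(sq.mean()), path=list(path))
        best = fit
        prev_codebook = codebook
        if fit.avg_distortion < distortion_cut:
            return fit
    warnings.warn("distortion cut unreachable; returning the finest grid")
    return best  # type: ignore[return-value]


def cluster_summaries(fit: SOMFit, nfc: pd.DataFrame,
                      n_eval: int | None = None) -> pd.DataFrame:
    """Smoothed mean trajectory per occupied SOM unit.

    The member-mean trajectory is smoothed with a shape-preserving local
    cubic (PCHIP) — the small-n limit of a local-regression smooth: with the
    handful of observed days available it interpolates the cluster mean at
    the days, reproduces linear trends exactly, and never introduces
    spurious non-monotonicity.  Rows: evaluation days (the nFC columns by
    default, or ``n_eval`` points spanning them); columns: occupied units.
    """
    days = np.asarray(nfc.columns, dtype=float)
    xs = days if n_eval is None else np.linspace(days[0], days[-1], n_eval)
    out = {}
    for u in sorted(fit.membership.unique()):
        members = nfc.loc[fit.membership[fit.membership == u].index]
        mean_traj = members.mean(axis=0).to_numpy(dtype=float)
        out[u] = PchipInterpolator(days, mean_traj)(xs)
    return pd.DataFrame(out, index=xs)
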