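"""Differential co-expression network classification (common / different /
specific links).

Given two or more significance-filtered wTO edge lists over a shared node
set, every link present in at least one network is classified:

* **alpha** — present in all networks with the same sign (common),
* **beta**  — present in at least two networks with differing signs
  (different),
* **gamma** — present in only a strict subset of the networks with a
  consistent sign (specific; with two networks this means exactly one).

Each network's weights are scaled by its own maximum absolute weight; a
link's score is its normalized distance from the origin in the joint weight
space, ||w~|| / sqrt(#networks), and only links with distance above the cut
(default 0.5) are kept.  Nodes are then categorised by a chi-square
goodness-of-fit of their kept-link category counts against uniform thirds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ripnet.containers import ExpressionMatrix

CATEGORIES = ("alpha", "beta", "gamma")


def classify_links(networks: Sequence[pd.DataFrame],
                   distance_cut: float = 0.5,
                   names: Sequence[str] | None = None) -> pd.DataFrame:
    """Classify links of >= 2 edge lists; returns the kept-link table.

    Each edge list needs columns node_i, node_j, omega (links absent from a
    network have weight 0 there).  Output columns: node_i, node_j, one
    ``w_<name>`` scaled weight per network, category, distance, kept,
    specific_to (the owning network for gamma links, else "").  Only rows
    with distance > distance_cut have ``kept=True``.
    """
    if len(networks) < 2:
        raise ValueError("need at least two networks")
    names = list(names) if names is not None else [f"net{i + 1}" for i in range(len(networks))]

    weights: dict[tuple[str, str], np.ndarray] = {}
    for k, net in enumerate(networks):
        maxw = net["omega"].abs().max() if len(net) else 0.0
        for _, row in net.iterrows():
            key = tuple(sorted((row["node_i"], row["node_j"])))
            w = weights.setdefault(key, np.zeros(len(networks)))
            w[k] = row["omega"] / maxw if maxw > 0 else 0.0

    rows = []
    for (ni, nj), w in sorted(weights.items()):
        present = w != 0.0
        n_present = int(present.sum())
        if n_present == 0:
            continue
        signs = set(np.sign(w[present]))
        if n_present == len(networks) and len(signs) == 1:
            cat = "alpha"
        elif n_present >= 2 and len(signs) > 1:
            cat = "beta"
        else:
            cat = "gamma"
        specific = names[int(np.flatnonzero(present)[0])] if n_present == 1 else ""
        dist = float(np.linalg.norm(w) / np.sqrt(len(networks)))
        rows.append((ni, nj, *w, cat, dist, dist > distance_cut, specific))

    cols = (["node_i", "node_j"] + [f"w_{n}" for n in names]
            + ["category", "distance", "kept", "specific_to"])
    out = pd.DataFrame(rows, columns=cols)
    return out


def kept_links(links: pd.DataFrame) -> pd.DataFrame:
    return links[links["kept"]].reset_index(drop=True)


@dataclass
class NodeCall:
    node: str
    counts: dict[str, int]
    chi2: float
    pvalue: float
    assigned: str            # alpha | beta | gamma | undefined
    low_expected: bool       # chi-square expected count < 5 flag

    @property
    def degree(self) -> int:
        return sum(self.counts.values())


def classify_nodes(links: pd.DataFrame, alpha: float = 0.05) -> list[NodeCall]:
    """Chi-square category call per node over its kept links.

    The node's category counts are tested against uniform thirds (df=2); a
    significant node gets its modal category, modal ties or non-significant
    fits give "undefined".  Expected counts < 5 are flagged but still tested.
    """
    kept = links[links["kept"]] if "kept" in links else links
    out = []
    nodes = sorted(set(kept["node_i"]) | set(kept["node_j"]))
    for node in nodes:
        sub = kept[(kept["node_i"] == node) | (kept["node_j"] == node)]
        counts = {c: int((sub["category"] == c).sum()) for c in CATEGORIES}
        deg = sum(counts.values())
        obs = np.array([counts[c] for c in CATEGORIES], dtype=float)
        exp = deg / 3.0
        chi2 = float(((obs - exp) ** 2 / exp).sum()) if deg else 0.0
        pval = float(stats.chi2.sf(chi2, df=2)) if deg else 1.0
        if pval < alpha:
            top = obs.max()
            modal = [c for c, o in zip(CATEGORIES, obs) if o == top]
            assigned = modal[0] if len(modal) == 1 else "undefined"
        else:
            assigned = "undefined"
        out.append(NodeCall(node, counts, chi2, pval, assigned, exp < 5))
    return out


def node_table(calls: Sequence[NodeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.node, c.counts["alpha"], c.counts["beta"], c.counts["gamma"],
          c.chi2, c.pvalue, c.assigned, c.low_expected) for c in calls],
        columns=["node", "n_alpha", "n_beta", "n_gamma", "chi2", "pvalue",
                 "assigned", "low_expected"],
    )


def correlated_gene_sets(expr: ExpressionMatrix,
                         node_calls: Sequence[NodeCall] | Sequence[str],
                         r_min: float = 0.9) -> dict[str, list[str]]:
    """Genes whose |Pearson r| with a categorised TF exceeds ``r_min``.

    ``expr`` should already be restricted to the relevant condition (and
    optionally day).  The TF itself is excluded from its own set.
    """
    tfs = [c.node if isinstance(c, NodeCall) else c for c in node_calls]
    x = expr.values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf
    z = (x - mu) / (sd * np.sqrt(x.shape[1]))
    genes = list(expr.genes)
    lookup = {g: i for i, g in enumerate(genes)}
    out = {}
    for tf in tfs:
        if tf not in lookup:
            out[tf] = []
            continue
        r = z @ z[lookup[tf]]
        hits = [g for g, ri in zip(genes, r) if abs(ri) > r_min and g != tf]
        out[tf] = sorted(hits)
    return out


def category_summary(links: pd.DataFrame) -> dict[str, int]:
    kept = links[links["kept"]]
    return {c: int((kept["category"] == c).sum()) for c in CATEGORIES}
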