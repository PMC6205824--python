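"""Signed wTO: formula oracle, bounds, expression filter, bootstrap."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from ripnet.containers import ExpressionMatrix
from ripnet.wto import (WTOParams, filter_expressed, significant_links, wto,
                        wto_bootstrap, wto_from_correlation)
from tests.conftest import make_expr


def oracle_wto(corr, nodes):
    """Triple-loop literal evaluation of the signed wTO definition."""
    G = corr.shape[0]
    n = len(nodes)
    omega = np.zeros((n, n))
    for a, i in enumerate(nodes):
        for b, j in enumerate(nodes):
            if i == j:
                continue
            num = sum(corr[i, u] * corr[u, j] for u in range(G) if u not in (i, j))
            num += corr[i, j]
            k_i = sum(abs(corr[i, u]) for u in range(G) if u != i)
            k_j = sum(abs(corr[j, u]) for u in range(G) if u != j)
            omega[a, b] = num / (min(k_i, k_j) + 1 - abs(corr[i, j]))
    return omega


def test_hand_evaluated_single_background_examples():
    # nodes i, j plus one background gene u with a_iu = a_ju = a_ij = 1
    c = np.ones((3, 3))
    omega = wto_from_correlation(c, [0, 1])
    assert omega[0, 1] == pytest.approx(1.0)

    # a_ij = 0.5, a_iu = 0.8, a_ju = -0.5
    c = np.array([[1.0, 0.5, 0.8],
                  [0.5, 1.0, -0.5],
                  [0.8, -0.5, 1.0]])
    omega = wto_from_correlation(c, [0, 1])
    # (0.8 * -0.5 + 0.5) / (min(1.3, 1.0) + 1 - 0.5) = 0.1 / 1.5
    assert omega[0, 1] == pytest.approx(0.1 / 1.5)


def test_zero_correlations_give_zero_wto():
    c = np.eye(8)
    omega = wto_from_correlation(c, [0, 1, 2])
    assert np.allclose(omega, 0.0)


def _random_correlation(rng, g, n_samples=None):
    """Correlation matrix of random data (valid, possibly near-singular)."""
    x = rng.normal(size=(g, n_samples or rng.integers(4, 12)))
    return np.corrcoef(x)


def test_wto_matches_triple_loop_oracle():
    rng = np.random.default_rng(2)
    for _ in range(30):
        g = int(rng.integers(4, 21))
        n_nodes = int(rng.integers(2, min(7, g + 1)))
        corr = _random_correlation(rng, g)
        nodes = list(rng.choice(g, size=n_nodes, replace=False))
        got = wto_from_correlation(corr, nodes)
        expected = oracle_wto(corr, nodes)
        assert np.allclose(got, expected, atol=1e-12)


def test_wto_on_data_matches_oracle_on_its_correlation_matrix():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(12, 9))
    em = make_expr(x, [f"g{i}" for i in range(12)])
    links = wto(em, ["g0", "g1", "g2"])
    corr = np.corrcoef(x)
    expected = oracle_wto(corr, [0, 1, 2])
    for row in links.itertuples():
        i, j = int(row.node_i[1:]), int(row.node_j[1:])
        assert row.omega == pytest.approx(expected[i, j], abs=1e-12)


def test_symmetry_and_unit_bound_on_random_structures():
    rng = np.random.default_rng(4)
    for _ in range(400):
        g = int(rng.integers(3, 15))
        corr = _random_correlation(rng, g)
        omega = wto_from_correlation(corr, list(range(min(g, 5))))
        assert np.allclose(omega, omega.T, atol=1e-12)
        assert np.all(np.abs(omega) <= 1.0 + 1e-12)


def test_zero_variance_gene_warns_and_gets_zero_correlation():
    x = np.vstack([np.random.default_rng(0).normal(size=(3, 6)),
                   np.full((1, 6), 3.0)])
    em = make_expr(x, ["a", "b", "c", "flat"])
    with pytest.warns(UserWarning, match="zero-variance"):
        links = wto(em, ["a", "flat"])
    assert links.loc[0, "omega"] == pytest.approx(0.0, abs=1e-12)


def test_too_few_samples_raise():
    em = make_expr(np.ones((3, 2)), ["a", "b", "c"])
    with pytest.raises(ValueError):
        wto(em, ["a", "b"])
    with pytest.raises(ValueError):
        wto_bootstrap(make_expr(np.ones((3, 3)), ["a", "b", "c"]), ["a", "b"])


# ---------------------------------------------------------------------------
# expression filter


def test_filter_expressed_rules(small_expr):
    """Zero gene removed; gene reaching the floor on one day kept."""
    out = filter_expressed(small_expr, rpkm_min=5.0)
    assert "g3" not in out.genes          # all-zero
    assert "g1" in out.genes              # well above
    assert "g2" in out.genes              # day mean 6.0 >= 5 in one group
    out2 = filter_expressed(small_expr, rpkm_min=10.0)
    assert list(out2.genes) == ["g1"]     # WT mean exactly 10.0 kept (>=)


def test_filter_expressed_enumeration(expression_data):
    _, rpkm, gt = expression_data
    out = filter_expressed(rpkm, 5.0)
    # the planted low-expression block is exactly what gets removed
    assert set(rpkm.genes) - set(out.genes) == set(gt.low_expressed)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_deterministic_and_perfect_pair_retained():
    rng = np.random.default_rng(5)
    base = rng.normal(size=7)
    x = np.vstack([base, base * 2.0 + 1.0, rng.normal(size=(6, 7))])
    em = make_expr(x, [f"g{i}" for i in range(8)])
    p = WTOParams(n_bootstrap=100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = wto_bootstrap(em, ["g0", "g1", "g2"], p, seed=42)
        b = wto_bootstrap(em, ["g0", "g1", "g2"], p, seed=42)
    pd.testing.assert_frame_equal(a, b)
    perfect = a[(a.node_i == "g0") & (a.node_j == "g1")]
    assert perfect["pval"].iloc[0] == 0.0
    assert len(significant_links(a, 0.10)) >= 1


def test_params_validation():
    with pytest.raises(ValueError):
        WTOParams(n_bootstrap=0)
    with pytest.raises(ValueError):
        WTOParams(p_cut=1.5)
    with pytest.raises(ValueError):
        WTOParams(correlation="spearman")


def test_planted_modules_have_higher_wto_than_between(expression_data):
    _, rpkm, gt = expression_data
    expressed = filter_expressed(rpkm, 5.0)
    sub = expressed.subset("WT", 3)
    tfs = [g for g in expressed.genes if g.startswith("TF")]
    links = wto(sub, tfs)
    module_of = {}
    for name, mod in gt.planted_modules.items():
        for tf in mod["tfs"]:
            module_of[tf] = name
    within = links[[module_of[r.node_i] == module_of[r.node_j]
                    for r in links.itertuples()]]
    between = links[[module_of[r.node_i] != module_of[r.node_j]
                     for r in links.itertuples()]]
    assert np.abs(within["omega"]).median() > np.abs(between["omega"]).quantile(0.95)
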