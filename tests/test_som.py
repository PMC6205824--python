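"""Persistent-DE selection, SOM fitting and trajectory summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ripnet.som import cluster_summaries, fit_som, persistent_de_tfs
from ripnet.targets import de_test


def _de(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue", "padj"])


def test_tf_significant_on_three_of_four_days_is_excluded():
    tfs = ["t1", "t2"]
    tables = {}
    for d in (1, 2, 3, 4):
        p2 = 0.01 if d < 4 else 0.5  # t2 misses day 4
        tables[d] = _de([("t1", 1.0 * d, 1e-4, 1e-3), ("t2", 1.0, 1e-4, p2)])
    nfc = persistent_de_tfs(tables, tfs)
    assert list(nfc.index) == ["t1"]
    assert list(nfc.columns) == [1, 2, 3, 4]


def test_empty_de_tables_give_empty_output():
    tables = {d: _de([]) for d in (1, 2)}
    assert persistent_de_tfs(tables, ["t1"]).empty


def test_nfc_is_standardised_per_day():
    tables = {d: _de([(f"t{i}", float(i * d), 1e-4, 1e-3) for i in range(5)])
              for d in (1, 2)}
    nfc = persistent_de_tfs(tables, [f"t{i}" for i in range(5)])
    assert np.allclose(nfc.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(nfc.std(axis=0, ddof=0), 1.0, atol=1e-12)


def test_planted_persistent_tfs_recovered_exactly(expression_data):
    counts, _, gt = expression_data
    days = (1, 2, 3, 4)
    tables = {d: de_test(counts, ("WT", "KO"), timepoint=d) for d in days}
    tfs = [g for g in counts.genes if g.startswith("TF")]
    nfc = persistent_de_tfs(tables, tfs)
    assert set(nfc.index) == set(gt.planted_clusters)


# ---------------------------------------------------------------------------
# SOM


def _two_shape_data(n=10, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    up = np.linspace(0, 1, 4) + rng.normal(0, noise, (n, 4))
    dn = np.linspace(1, 0, 4) + rng.normal(0, noise, (n, 4))
    nfc = pd.DataFrame(np.vstack([up, dn]),
                       index=[f"g{i}" for i in range(2 * n)],
                       columns=[1, 2, 3, 4])
    return nfc, [0] * n + [1] * n


def test_two_separated_shapes_recovered_with_two_units():
    nfc, labels = _two_shape_data()
    fit = fit_som(nfc, seed=1, distortion_cut=0.2)
    assert fit.grid == (1, 2)
    assert adjusted_rand_score(labels, fit.membership.to_numpy()) == 1.0


def test_identical_trajectories_one_unit_zero_distortion():
    nfc = pd.DataFrame(np.tile([0.0, 1.0, 2.0, 3.0], (6, 1)),
                       index=[f"g{i}" for i in range(6)], columns=[1, 2, 3, 4])
    fit = fit_som(nfc, seed=0, distortion_cut=10.0)
    assert fit.membership.nunique() == 1
    assert fit.avg_distortion == pytest.approx(0.0, abs=1e-12)


def test_som_deterministic_under_seed():
    nfc, _ = _two_shape_data(seed=5)
    a = fit_som(nfc, seed=9, distortion_cut=0.2)
    b = fit_som(nfc, seed=9, distortion_cut=0.2)
    pd.testing.assert_series_equal(a.membership, b.membership)
    assert np.array_equal(a.codebook, b.codebook)


def test_distortion_non_increasing_along_growth_path():
    rng = np.random.default_rng(3)
    x = np.vstack([rng.normal(loc=m, scale=0.3, size=(8, 4))
                   for m in (-2, 0, 2)])
    nfc = pd.DataFrame(x, index=[f"g{i}" for i in range(len(x))],
                       columns=[1, 2, 3, 4])
    fit = fit_som(nfc, seed=1, distortion_cut=1e-4)  # forces a long path
    dists = [d for _, d in fit.path]
    assert len(dists) >= 4
    assert all(b <= a + 1e-9 for a, b in zip(dists, dists[1:]))


def test_unreachable_cut_returns_finest_grid_with_warning():
    nfc, _ = _two_shape_data(n=3, noise=0.4, seed=2)
    with pytest.warns(UserWarning, match="unreachable"):
        fit = fit_som(nfc, seed=0, distortion_cut=0.0)
    assert fit.n_units == len(nfc)
    assert fit.avg_distortion == pytest.approx(0.0, abs=1e-12)


def test_fewer_than_two_trajectories_rejected():
    nfc = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=[1, 2])
    with pytest.raises(ValueError):
        fit_som(nfc)


def test_som_recovers_planted_trajectory_labels(expression_data):
    counts, _, gt = expression_data
    tables = {d: de_test(counts, ("WT", "KO"), timepoint=d) for d in (1, 2, 3, 4)}
    tfs = [g for g in counts.genes if g.startswith("TF")]
    nfc = persistent_de_tfs(tables, tfs)
    fit = fit_som(nfc, seed=11, distortion_cut=0.2)
    labels = [gt.planted_clusters[g] for g in nfc.index]
    assert adjusted_rand_score(labels, fit.membership.to_numpy()) >= 0.9


# ---------------------------------------------------------------------------
# summaries


def test_single_member_cluster_smooth_interpolates_member():
    nfc = pd.DataFrame([[0.0, 2.0, 1.0, 3.0],
                        [0.1, 2.1, 1.1, 3.1]],
                       index=["a", "b"], columns=[1, 2, 3, 4])
    fit = fit_som(nfc, seed=0, distortion_cut=10.0)
    # force two singleton clusters to exercise interpolation
    if fit.membership.nunique() == 1:
        fit = fit_som(nfc, seed=0, distortion_cut=1e-6)
    summ = cluster_summaries(fit, nfc)
    for unit in summ.columns:
        members = nfc.loc[fit.membership[fit.membership == unit].index]
        assert np.allclose(summ[unit].to_numpy(),
                           members.mean(axis=0).to_numpy(), atol=1e-9)


def test_linear_trajectories_smooth_to_the_line():
    nfc = pd.DataFrame(np.vstack([np.linspace(0, 3, 4)] * 4),
                       index=list("abcd"), columns=[1, 2, 3, 4])
    fit = fit_som(nfc, seed=0, distortion_cut=10.0)
    summ = cluster_summaries(fit, nfc, n_eval=7)
    xs = summ.index.to_numpy()
    assert np.allclose(summ.iloc[:, 0].to_numpy(), xs - 1.0, atol=1e-9)


def test_rising_cluster_smooth_is_increasing(expression_data):
    counts, _, gt = expression_data
    tables = {d: de_test(counts, ("WT", "KO"), timepoint=d) for d in (1, 2, 3, 4)}
    tfs = [g for g in counts.genes if g.startswith("TF")]
    nfc = persistent_de_tfs(tables, tfs)
    fit = fit_som(nfc, seed=11, distortion_cut=0.2)
    summ = cluster_summaries(fit, nfc)
    rising = [g for g, s in gt.planted_clusters.items()
              if s == "rising" and g in fit.membership.index]
    unit = fit.membership[rising].mode().iloc[0]
    vals = summ[unit].to_numpy()
    assert np.all(np.diff(vals) > 0)
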