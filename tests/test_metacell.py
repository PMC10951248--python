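"""Metacell clustering: feature selection, graphs, co-occurrence,
partitions and the 2D projection."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import xatlas as xa
from xatlas.metacell import (
    OUTLIER,
    AllOutliersError,
    _balanced_knn,
    metacell_graph,
    seed_and_grow,
)


def _matrix(counts: np.ndarray) -> xa.UmiMatrix:
    n, f = counts.shape
    cells = pd.DataFrame(
        {"plate": 0, "well": range(n)},
        index=pd.Index([f"c{i:04d}" for i in range(n)], name="barcode"),
    )
    feats = pd.DataFrame({"kind": "gene"},
                         index=pd.Index([f"g{j}" for j in range(f)], name="id"))
    m = xa.UmiMatrix(sp.csr_matrix(counts), cells, feats)
    m.cells["total_umis"] = m.host_totals()
    return m


def _two_pop_counts(n_per=200, n_genes=40, depth=300, fold=10, seed=0):
    """Two planted populations with disjoint strong marker blocks."""
    rng = np.random.default_rng(seed)
    w = np.ones((2, n_genes))
    w[0, :5] = fold
    w[1, 5:10] = fold
    w = w / w.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, w[t], size=n_per)
                        for t in (0, 1)])
    labels = np.repeat([0, 1], n_per)
    return counts, labels


# ---------------------------------------------------------------------------
# feature selection

def test_feature_umi_threshold_is_strict():
    # g0 totals exactly 100, g1 101, g2 plenty
    counts = np.zeros((50, 3), dtype=int)
    counts[:, 0] = 2
    counts[:25, 1] = 3
    counts[25:, 1] = 1  # wait: totals
    counts[:, 1] = 0
    counts[:50, 1] = 2
    counts[0, 1] += 1
    counts[:, 2] = 10
    m = _matrix(counts)
    assert counts[:, 0].sum() == 100 and counts[:, 1].sum() == 101
    feats = xa.select_features(m, xa.MetacellParams(seed=0))
    assert "g0" not in feats
    assert "g1" in feats and "g2" in feats


def test_depth_artifact_feature_excluded_by_default_direction():
    """A feature whose normalized share falls with cell depth (a depth
    artifact) is excluded under the default direction (corr >= -0.05);
    flipping the flag selects it instead."""
    rng = np.random.default_rng(0)
    n = 400
    scale = np.repeat([1, 3], n // 2)  # depth varies 3x between halves
    counts = rng.poisson(5 * scale[:, None], size=(n, 30))
    # g0, g1 expressed mostly in shallow cells: share anticorrelated with depth
    for j in (0, 1):
        counts[:, j] = np.where(scale == 1, rng.poisson(40, n),
                                rng.poisson(2, n))
    m = _matrix(counts)
    sel_default = xa.select_features(m, xa.MetacellParams(seed=1))
    sel_flipped = xa.select_features(
        m, xa.MetacellParams(seed=1, szcor_select_above=False)
    )
    assert "g0" not in sel_default
    assert "g5" in sel_default
    assert "g0" in sel_flipped


def test_too_few_features_rejected():
    m = _matrix(np.ones((20, 2), dtype=int))
    with pytest.raises(ValueError):
        xa.select_features(m, xa.MetacellParams(seed=0))


def test_planted_markers_all_selected(clustered_run):
    truth_genes = clustered_run.truth.genes
    markers = set(truth_genes.loc[truth_genes["marker_of"] >= 0, "id"])
    selected = set(xa.select_features(clustered_run.retained,
                                      clustered_run.params))
    assert markers <= selected


# ---------------------------------------------------------------------------
# balanced kNN

def test_identical_cells_give_complete_digraph():
    counts = np.tile([5, 5, 5, 5], (3, 1))
    m = _matrix(counts)
    g = xa.build_balanced_knn(m, ["g0", "g1", "g2", "g3"],
                              xa.MetacellParams(k_graph=2, seed=0))
    g = g.toarray()
    assert (np.diag(g) == 0).all()
    assert ((g > 0).sum(axis=1) == 2).all()


def test_degree_caps_hold():
    counts, _ = _two_pop_counts(n_per=100, seed=1)
    m = _matrix(counts)
    feats = [f"g{j}" for j in range(counts.shape[1])]
    p = xa.MetacellParams(k_graph=15, seed=1)
    g = xa.build_balanced_knn(m, feats, p)
    out_deg = np.asarray((g > 0).sum(axis=1)).ravel()
    in_deg = np.asarray((g > 0).sum(axis=0)).ravel()
    assert (out_deg <= 15).all()
    assert (in_deg <= 45).all()


def test_separated_populations_rarely_connect():
    counts, labels = _two_pop_counts(seed=2)
    m = _matrix(counts)
    feats = [f"g{j}" for j in range(counts.shape[1])]
    g = xa.build_balanced_knn(m, feats, xa.MetacellParams(k_graph=20, seed=2))
    src, dst = g.nonzero()
    cross = (labels[src] != labels[dst]).mean()
    assert cross < 0.01


def test_balanced_knn_in_degree_pruning_keeps_best():
    # hub similarity: node 0 similar to everyone; cap forces pruning
    S = np.full((6, 6), 0.1)
    np.fill_diagonal(S, 1.0)
    S[0, :] = S[:, 0] = 0.9
    np.fill_diagonal(S, 1.0)
    g = _balanced_knn(S, k=3, in_cap=2)
    in_deg = np.asarray((g > 0).sum(axis=0)).ravel()
    assert (in_deg <= 2).all()


# ---------------------------------------------------------------------------
# seed-and-grow and co-occurrence

def test_seed_and_grow_covers_subset_deterministically():
    counts, _ = _two_pop_counts(n_per=60, seed=3)
    m = _matrix(counts)
    feats = [f"g{j}" for j in range(counts.shape[1])]
    g = xa.build_balanced_knn(m, feats, xa.MetacellParams(k_graph=10, seed=3))
    subset = np.arange(0, 120, 2)
    l1 = seed_and_grow(g, subset, target_size=20)
    l2 = seed_and_grow(g, subset, target_size=20)
    assert np.array_equal(l1, l2)
    assert (l1 >= 0).all()
    assert len(l1) == len(subset)


def test_single_resample_full_fraction_is_binary():
    counts, _ = _two_pop_counts(n_per=50, seed=4)
    m = _matrix(counts)
    feats = [f"g{j}" for j in range(counts.shape[1])]
    p = xa.MetacellParams(k_graph=10, n_resamples=1, resample_frac=1.0,
                          mc_target_size=25, seed=4)
    g = xa.build_balanced_knn(m, feats, p)
    coc = xa.resampled_cooccurrence(g, p)
    vals = np.unique(coc.freq)
    assert set(vals) <= {0.0, 1.0}
    labels = seed_and_grow(g, np.arange(100), 25)
    same = labels[:, None] == labels[None, :]
    assert np.array_equal(coc.freq == 1.0, same)


def test_cooccurrence_bounds_and_symmetry(clustered_run):
    coc = clustered_run.results.cooccurrence
    assert coc.freq.min() >= 0.0 and coc.freq.max() <= 1.0
    assert np.allclose(coc.freq, coc.freq.T)
    assert (np.diag(coc.freq) == 1.0).all()


def test_cooccurrence_separates_planted_clusters():
    counts, labels = _two_pop_counts(seed=5)
    m = _matrix(counts)
    feats = [f"g{j}" for j in range(counts.shape[1])]
    p = xa.MetacellParams(k_graph=20, n_resamples=100, mc_target_size=100,
                          seed=5)
    g = xa.build_balanced_knn(m, feats, p)
    coc = xa.resampled_cooccurrence(g, p)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    within = coc.freq[same & off].mean()
    between = coc.freq[~same].mean()
    assert within > 0.9
    assert between < 0.1


def test_duplicated_cells_cooccur_with_binomial_error():
    """On near-duplicate cells the co-occurrence estimator approaches 1."""
    rng = np.random.default_rng(6)
    base = rng.multinomial(400, np.ones(30) / 30)
    counts = np.tile(base, (80, 1)) + rng.poisson(0.5, size=(80, 30))
    m = _matrix(counts)
    feats = [f"g{j}" for j in range(30)]
    p = xa.MetacellParams(k_graph=10, n_resamples=200, mc_target_size=100,
                          min_feature_umis=0, seed=6)
    g = xa.build_balanced_knn(m, feats, p)
    coc = xa.resampled_cooccurrence(g, p)
    off = ~np.eye(80, dtype=bool)
    assert coc.freq[off].mean() > 0.95


# ---------------------------------------------------------------------------
# final partition

def test_too_few_cells_all_outliers():
    rng = np.random.default_rng(7)
    freq = np.clip(rng.random((25, 25)), 0, 1)
    freq = (freq + freq.T) / 2
    np.fill_diagonal(freq, 1.0)
    coc = xa.CoOccurrence(freq, np.full((25, 25), 10), 10)
    p = xa.MetacellParams(min_mc_size=30, seed=7)
    part = xa.final_partition(coc, p, on_all_outliers="return")
    assert (part.assignments == OUTLIER).all()
    with pytest.raises(AllOutliersError):
        xa.final_partition(coc, p)


def test_two_type_mixture_recovered_exactly():
    counts, labels = _two_pop_counts(seed=8)
    m = _matrix(counts)
    p = xa.MetacellParams(k_graph=30, n_resamples=150, mc_target_size=100,
                          seed=8)
    res = xa.MetacellModel(m, p).fit()
    a = res.partition.assignments
    assert (a != OUTLIER).all()
    maj = pd.DataFrame({"mc": a, "t": labels}).groupby("mc")["t"].agg(
        lambda s: s.value_counts().index[0]
    )
    ari = adjusted_rand_score(labels, pd.Series(a).map(maj))
    assert ari == 1.0
    assert res.partition.sizes.min() >= p.min_mc_size


def test_partition_covers_every_cell_once(clustered_run):
    part = clustered_run.results.partition
    a = part.assignments
    assert len(a) == clustered_run.retained.counts.shape[0]
    assert set(np.unique(a)) <= set([OUTLIER] + list(range(1, part.n_metacells + 1)))
    assert part.sizes.min() >= clustered_run.params.min_mc_size


def test_same_seed_identical_fit(clustered_run):
    res2 = xa.MetacellModel(clustered_run.retained,
                            clustered_run.params).fit()
    r1 = clustered_run.results
    assert np.array_equal(r1.partition.assignments,
                          res2.partition.assignments)
    assert np.array_equal(r1.cooccurrence.freq, res2.cooccurrence.freq)
    assert np.allclose(r1.partition.cell_coords,
                       res2.partition.cell_coords, equal_nan=True)


# ---------------------------------------------------------------------------
# projection

def test_layout_degree_cap_and_coordinates(clustered_run):
    res = clustered_run.results
    G = metacell_graph(res.partition, res.cooccurrence, clustered_run.params)
    assert max((d for _, d in G.degree), default=0) <= 4
    xy = res.partition.cell_coords
    ok = res.partition.assignments != OUTLIER
    assert np.isfinite(xy[ok]).all()


def test_single_metacell_layout_clusters_near_centroid():
    counts = np.tile(np.arange(1, 21), (60, 1))
    rng = np.random.default_rng(9)
    counts = counts + rng.poisson(1, size=counts.shape)
    m = _matrix(counts)
    p = xa.MetacellParams(k_graph=10, n_resamples=50, mc_target_size=100,
                          min_feature_umis=0, seed=9)
    res = xa.MetacellModel(m, p).fit()
    assert res.n_metacells == 1
    xy = res.partition.cell_coords
    assert np.nanmax(np.abs(xy)) < 0.2


def test_summary_mentions_counts(clustered_run):
    s = clustered_run.results.summary()
    assert f"metacells:             {clustered_run.results.n_metacells}" in s
    assert "seed=5" in s
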