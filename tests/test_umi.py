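"""UMI collapse, IVT-artifact filtering and retention thresholds."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import xatlas as xa
from conftest import tiny_config


# ---------------------------------------------------------------------------
# oracle: independent directional-merge cluster count

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def directional_oracle(umis: dict[str, int], ratio: float = 2.0) -> int:
    """Brute-force cluster count: enumerate every UMI pair to build the
    directed merge graph (a -> b when Hamming = 1 and
    reads(a) >= ratio * reads(b) - 1), then peel clusters from the
    highest-read unvisited UMI by full reachability."""
    names = sorted(umis)
    edges = {a: set() for a in names}
    for a, b in itertools.permutations(names, 2):
        if _hamming(a, b) == 1 and umis[a] >= ratio * umis[b] - 1:
            edges[a].add(b)
    visited: set[str] = set()
    clusters = 0
    for root in sorted(names, key=lambda u: (-umis[u], u)):
        if root in visited:
            continue
        clusters += 1
        frontier = {root}
        while frontier:
            visited |= frontier
            frontier = {b for a in frontier for b in edges[a]} - visited
    return clusters


def _table(groups: dict[tuple[str, str], dict[str, int]]) -> pd.DataFrame:
    rows = []
    for (bc, feat), umis in groups.items():
        for umi, reads in umis.items():
            rows.append((bc, 0, 0, feat, umi, reads, 1))
    return pd.DataFrame(
        rows,
        columns=["barcode", "plate", "well", "feature_id", "umi", "reads",
                 "n_pos"],
    )


def _features(ids):
    return pd.DataFrame({"id": list(ids), "kind": "gene"})


def _counts(table, feats):
    m = xa.collapse_umis(table, _features(feats))
    return np.asarray(m.counts.todense())


# ---------------------------------------------------------------------------
# collapse

def test_single_mismatch_low_read_umi_absorbed():
    c = _counts(_table({("c0", "g0"): {"AAAA": 10, "AAAT": 1}}), ["g0"])
    assert c.sum() == 1


def test_distant_umis_not_merged():
    c = _counts(_table({("c0", "g0"): {"AAAA": 5, "TTTT": 5}}), ["g0"])
    assert c.sum() == 2


def test_directional_threshold_blocks_balanced_pair():
    # reads(a)=5 < 2*4-1=7: no merge either way
    c = _counts(_table({("c0", "g0"): {"AAAA": 5, "AAAT": 4}}), ["g0"])
    assert c.sum() == 2


def test_merge_is_per_group_not_global():
    t = _table({("c0", "g0"): {"AAAA": 10},
                ("c1", "g0"): {"AAAT": 1},
                ("c0", "g1"): {"AAAT": 1}})
    c = _counts(t, ["g0", "g1"])
    assert c.sum() == 3


def test_unequal_umi_lengths_rejected():
    t = _table({("c0", "g0"): {"AAAA": 1, "AAAAA": 1}})
    with pytest.raises(ValueError, match="unequal length"):
        xa.collapse_umis(t, _features(["g0"]))


def test_collapse_disabled_counts_distinct_umis():
    t = _table({("c0", "g0"): {"AAAA": 10, "AAAT": 1}})
    params = xa.FilterParams(collapse_enabled=False)
    m = xa.collapse_umis(t, _features(["g0"]), params)
    assert m.counts.sum() == 2


@pytest.mark.parametrize("seed", range(4))
def test_random_groups_match_directional_oracle(seed):
    """Random UMI multisets of <= 8 UMIs vs the exhaustive pairwise
    oracle, batched across many (cell, feature) groups."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    groups = {}
    expected = {}
    for gi in range(400):
        n_umis = int(rng.integers(1, 9))
        umis = {}
        while len(umis) < n_umis:
            # short UMIs make Hamming-1 pairs common
            u = "".join(rng.choice(list(bases)) for _ in range(3))
            umis.setdefault(u, int(rng.integers(1, 30)))
        key = (f"c{gi}", "g0")
        groups[key] = umis
        expected[key] = directional_oracle(umis)
    m = xa.collapse_umis(_table(groups), _features(["g0"]))
    got = pd.Series(
        np.asarray(m.counts.todense()).ravel(), index=m.cells.index
    )
    for (bc, _), want in expected.items():
        assert got[bc] == want, (bc, groups[(bc, "g0")])


def test_zero_error_collapse_recovers_planted_molecules():
    """With no UMI errors and long UMIs, molecule counts equal truth."""
    config = tiny_config(seed=21, n_plates=1, depth_median=80.0,
                         umi_error_rate=0.0, umi_length=12,
                         nonunique_rate=0.0, reads_per_umi=1.5)
    ann = xa.simulate_annotation(config)
    reads, truth = xa.simulate_reads(config, ann)
    ext = xa.extend_intervals(ann.features, ann.chrom_sizes)
    bins = xa.build_intergenic_bins(ext, ann.chrom_sizes, reads)
    asg = xa.assign_reads(reads, ext + bins)
    m = xa.collapse_umis(xa.build_umi_table(asg), ext + bins)
    got = pd.DataFrame(
        np.asarray(m.counts.todense()), index=m.cells.index,
        columns=m.features.index,
    )
    planted = truth.molecules
    annotated = set(truth.genes.loc[~truth.genes["hidden"], "id"])
    for row in planted.itertuples(index=False):
        if row.feature_id in annotated:
            assert got.loc[row.barcode, row.feature_id] == row.n_molecules


def test_molecules_never_exceed_reads(tiny_run):
    per_group_reads = tiny_run.umi_table.groupby(
        ["barcode", "feature_id"]
    )["reads"].sum()
    m = xa.collapse_umis(tiny_run.umi_table, tiny_run.features)
    counts = pd.DataFrame.sparse.from_spmatrix(
        m.counts, index=m.cells.index, columns=m.features.index
    ).sparse.to_dense()
    for (bc, feat), reads in per_group_reads.items():
        assert counts.loc[bc, feat] <= reads


# ---------------------------------------------------------------------------
# IVT artifact filter

def test_uniform_single_read_umis_not_removed():
    t = _table({("c0", "g0"): {u: 1 for u in ("AAAA", "CCCC", "GGGG")}})
    out, report = xa.filter_ivt_artifacts(t, xa.FilterParams())
    assert report["n_removed"] == 0
    assert len(out) == len(t)


def test_extreme_read_multiplicity_removed_and_matches_bh_oracle():
    """One 500-read UMI in a run averaging ~2 reads/UMI is removed; the
    removal set equals a hand-rolled binomial + BH computation."""
    rng = np.random.default_rng(0)
    umis = {f"{a}{b}{c}{d}": int(rng.integers(1, 4))
            for a in "ACGT" for b in "ACGT" for c in "AC" for d in "AG"}
    umis["TTTT"] = 500
    t = _table({("c0", "g0"): umis})
    params = xa.FilterParams()
    out, report = xa.filter_ivt_artifacts(t, params)
    removed = {r["umi"] for r in report["removed"]}
    assert "TTTT" in removed
    # oracle: binomial tail + Benjamini-Hochberg step-up
    reads = t["reads"].to_numpy()
    R, U = reads.sum(), len(reads)
    p = binom.sf(reads - 1, R, 1 / U)
    order = np.argsort(p, kind="stable")
    q = np.minimum.accumulate((p[order] * U / np.arange(1, U + 1))[::-1])[::-1]
    qvals = np.empty(U)
    qvals[order] = q
    want = set(t.loc[qvals < params.umi_fdr_q, "umi"])
    assert removed == want


def test_removals_monotone_in_q_threshold():
    rng = np.random.default_rng(1)
    umis = {}
    while len(umis) < 200:
        u = "".join(rng.choice(list("ACGT")) for _ in range(6))
        umis.setdefault(u, int(rng.geometric(0.4)))
    t = _table({("c0", "g0"): umis})
    removed = [
        xa.filter_ivt_artifacts(t, xa.FilterParams(umi_fdr_q=q))[1]["n_removed"]
        for q in (0.01, 0.05, 0.2, 0.5)
    ]
    assert removed == sorted(removed)


# ---------------------------------------------------------------------------
# cell / gene retention

def _matrix_from_totals(cell_totals, gene_kind="gene"):
    import scipy.sparse as sp
    counts = sp.csr_matrix(np.array(cell_totals)[:, None])
    cells = pd.DataFrame(
        {"plate": 0, "well": range(len(cell_totals))},
        index=pd.Index([f"c{i}" for i in range(len(cell_totals))],
                       name="barcode"),
    )
    feats = pd.DataFrame({"kind": [gene_kind]},
                         index=pd.Index(["g0"], name="id"))
    m = xa.UmiMatrix(counts, cells, feats)
    m.cells["total_umis"] = m.host_totals()
    return m


def test_cell_threshold_is_strict():
    m = _matrix_from_totals([100, 101, 4000])
    out, summary = xa.filter_cells_genes(m, xa.FilterParams())
    assert summary["retained_cells"] == 2
    assert set(out.cells["total_umis"]) == {101, 4000}


def test_gene_detection_threshold_inclusive_and_nondestructive():
    import scipy.sparse as sp
    counts = sp.csr_matrix(np.array([[9, 10]]))
    cells = pd.DataFrame({"plate": [0], "well": [0]},
                         index=pd.Index(["c0"], name="barcode"))
    feats = pd.DataFrame({"kind": "gene"},
                         index=pd.Index(["g0", "g1"], name="id"))
    m = xa.UmiMatrix(counts, cells, feats)
    m.cells["total_umis"] = m.host_totals()
    out, summary = xa.filter_cells_genes(m, xa.FilterParams(min_cell_umis=5))
    assert summary["detected_genes"] == 1
    assert out.features.loc["g1", "detected"]
    assert not out.features.loc["g0", "detected"]
    assert out.counts.shape[1] == 2  # features never dropped


def test_empty_matrix_rejected():
    import scipy.sparse as sp
    m = xa.UmiMatrix(
        sp.csr_matrix((0, 0)),
        pd.DataFrame(index=pd.Index([], name="barcode")),
        pd.DataFrame(index=pd.Index([], name="id"), columns=["kind"]),
    )
    with pytest.raises(ValueError):
        xa.filter_cells_genes(m, xa.FilterParams())


def test_retention_summary_matches_bruteforce(tiny_run):
    totals = tiny_run.matrix.host_totals()
    assert tiny_run.summary["retained_cells"] == int((totals > 100).sum())
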