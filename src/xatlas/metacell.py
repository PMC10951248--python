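"""Metacell clustering by bootstrapped graph partitioning.

Cells are grouped into metacells — small, transcriptionally homogeneous
clusters — in five stages:

1. feature selection: features with > 100 total molecules whose
   depth-scaling correlation passes a -0.05 threshold;
2. a balanced kNN cell graph (K = 150): Pearson similarity of
   log-transformed down-sampled counts, each cell keeping its K best
   neighbors, in-degree capped at 3K so hubs cannot dominate;
3. 1,000 graph partitions on independent 75% resamples of the cells,
   accumulated into a co-occurrence matrix (fraction of co-sampling
   events in which two cells co-clustered);
4. a final partition of a balanced kNN graph built on the co-occurrence
   values (K = 30, in-degree cap alpha*K with alpha = 2); clusters below
   min_mc_size = 30 are dissolved and their cells reassigned to the
   neighboring metacell with maximal mean co-occurrence;
5. a force-directed 2D projection of the metacell graph (kNN constant 20,
   module graph degree capped at 4).

Partitions use a seed-and-grow cover: the unassigned cell with maximal
weighted degree seeds a cluster, which grows along the strongest graph
connectivity to a target size. All randomness flows from one run seed;
ties break by (score, then cell id).

The stage functions are exposed individually; `MetacellModel` /
`MetacellResults` wrap them as a fit-once model over a `UmiMatrix`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import MetacellParams
from .umi import UmiMatrix

OUTLIER = -1


class AllOutliersError(ValueError):
    """Raised when the final partition leaves every cell an outlier."""


# ---------------------------------------------------------------------------
# helpers

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def downsample_depth(totals: np.ndarray, params: MetacellParams) -> int:
    """Common down-sampling depth: a low per-cell-total quantile, capped."""
    q = float(np.quantile(totals, params.downsample_quantile))
    return int(min(max(q, 1), params.downsample_cap))


def downsample_counts(counts: sp.spmatrix, target: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Down-sample each cell's counts to ``target`` molecules without
    replacement (cells below target keep all counts). Dense output."""
    dense = np.asarray(counts.todense(), dtype=np.int64)
    out = np.zeros_like(dense)
    for i in range(dense.shape[0]):
        row = dense[i]
        tot = int(row.sum())
        if tot <= target:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, target)
    return out


# ---------------------------------------------------------------------------
# stage 1: feature selection

def select_features(m: UmiMatrix, params: MetacellParams) -> list[str]:
    """Features eligible for clustering.

    A host feature (gene or rescued bin; bacterial genomes are excluded)
    is selected when its total exceeds ``min_feature_umis`` AND its
    depth-scaling correlation — Pearson correlation between the feature's
    down-sampled counts and log total cell depth — passes the threshold
    (default: correlation >= -0.05, i.e. strongly depth-anticorrelated
    features are treated as depth artifacts; direction flips with
    ``szcor_select_above=False``). Returned in decreasing variance/mean
    order (ties by id) for a deterministic feature ranking.
    """
    host = m.host_feature_mask
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    eligible = host & (totals > params.min_feature_umis)
    if eligible.sum() < 2:
        raise ValueError("fewer than 2 features pass the UMI threshold")

    cell_tot = m.host_totals().astype(float)
    depth = downsample_depth(cell_tot, params)
    D = downsample_counts(
        sp.csr_matrix(m.counts[:, eligible]), depth, _rng(params.seed, 10)
    ).astype(float)
    y = np.log(np.maximum(cell_tot, 1.0))
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    Xc = D - D.mean(axis=0, keepdims=True)
    x_ss = (Xc * Xc).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ yc) / np.sqrt(x_ss * y_ss)
    corr = np.nan_to_num(corr, nan=0.0)

    if params.szcor_select_above:
        pass_corr = corr >= params.szcor_threshold
    else:
        pass_corr = corr <= params.szcor_threshold

    mean = D.mean(axis=0)
    var = D.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vmr = np.where(mean > 0, var / mean, 0.0)

    ids = m.features.index.to_numpy()[eligible]
    sel = np.flatnonzero(pass_corr)
    if len(sel) < 2:
        raise ValueError("fewer than 2 features survive feature selection")
    order = sorted(sel, key=lambda i: (-vmr[i], str(ids[i])))
    return [str(ids[i]) for i in order]


# ---------------------------------------------------------------------------
# stage 2: balanced kNN graph

def _balanced_knn(S: np.ndarray, k: int, in_cap: int) -> sp.csr_matrix:
    """Directed rank-weighted kNN graph from a similarity matrix.

    Each node keeps its k best neighbors (edge weight (k - rank)/k);
    targets with in-degree above ``in_cap`` shed their worst-ranked
    incoming edges. Ties break by node id. No self-edges.
    """
    n = S.shape[0]
    S = S.copy()
    np.fill_diagonal(S, -np.inf)
    order = np.argsort(-S, axis=1, kind="stable")[:, :k]
    src = np.repeat(np.arange(n), k)
    dst = order.ravel()
    w = np.tile((k - np.arange(k)) / k, n)
    nonself = src != dst
    src, dst, w = src[nonself], dst[nonself], w[nonself]

    # in-degree balancing: keep the best `in_cap` incoming edges per target
    by_dst = np.lexsort((-w, dst))
    dst_s = dst[by_dst]
    first = np.concatenate(([True], dst_s[1:] != dst_s[:-1]))
    pos_in_group = np.arange(len(dst_s)) - np.maximum.accumulate(
        np.where(first, np.arange(len(dst_s)), 0)
    )
    keep = pos_in_group < in_cap
    sel = by_dst[keep]
    return sp.csr_matrix((w[sel], (src[sel], dst[sel])), shape=(n, n))


def build_balanced_knn(m: UmiMatrix, features: list[str],
                       params: MetacellParams) -> sp.csr_matrix:
    """Balanced kNN cell graph over the selected features.

    Similarity is the Pearson correlation of log2(1 + down-sampled
    counts); the directed graph keeps K = ``k_graph`` neighbors per cell
    with in-degree capped at 3K. If fewer than K+1 cells are present, K
    is reduced with a warning.
    """
    n = m.counts.shape[0]
    k = params.k_graph
    if n <= k:
        k = max(1, n - 1)
        warnings.warn(f"fewer cells than k_graph; reducing k to {k}")
    col = m.features.index.get_indexer(features)
    if (col < 0).any():
        raise KeyError("unknown feature ids in selection")
    sub = sp.csr_matrix(m.counts[:, col])
    depth = downsample_depth(m.host_totals().astype(float), params)
    D = downsample_counts(sub, depth, _rng(params.seed, 11))
    X = np.log2(1.0 + D)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.corrcoef(X)
    S = np.nan_to_num(np.atleast_2d(S), nan=0.0)
    return _balanced_knn(S, k, 3 * k)


# ---------------------------------------------------------------------------
# seed-and-grow graph cover

def seed_and_grow(W: sp.csr_matrix, subset: np.ndarray,
                  target_size: int, boundary_frac: float = 0.25,
                  cohesion_frac: float = 0.5) -> np.ndarray:
    """Partition the induced subgraph by seeded growth.

    Repeatedly seeds a cluster at the unassigned cell with maximal
    weighted degree (within the subset) and grows it by adding the
    unassigned cell with the strongest total connection to the cluster.
    Growth respects natural community boundaries: it always stops when
    the best candidate's connection drops below ``boundary_frac`` of the
    mean connection at which earlier members joined, and it continues
    past ``target_size`` only while the candidate stays above
    ``cohesion_frac`` of that mean — so a tight community larger than the
    target is kept whole, while loose growth stops at the target.
    Unreachable cells form singleton clusters. Deterministic: ties break
    by cell id. Returns local labels (0..n_clusters-1) per subset cell.
    """
    subset = np.sort(np.asarray(subset))
    Wl = sp.csr_matrix(W[np.ix_(subset, subset)])
    Wl = Wl + Wl.T
    n = len(subset)
    indptr, indices, data = Wl.indptr, Wl.indices, Wl.data
    static_deg = np.asarray(Wl.sum(axis=1)).ravel()

    labels = np.full(n, -1, dtype=np.int64)
    conn = np.zeros(n)
    unassigned = np.ones(n, dtype=bool)
    neg_inf = -np.inf
    cluster = 0
    n_left = n
    while n_left > 0:
        seed_scores = np.where(unassigned, static_deg, neg_inf)
        seed = int(seed_scores.argmax())
        labels[seed] = cluster
        unassigned[seed] = False
        n_left -= 1
        conn.fill(0.0)
        lo, hi = indptr[seed], indptr[seed + 1]
        conn[indices[lo:hi]] += data[lo:hi]
        size = 1
        join_sum = 0.0
        join_n = 0
        while n_left > 0:
            cand = np.where(unassigned, conn, neg_inf)
            nxt = int(cand.argmax())
            c = cand[nxt]
            if c <= 0:
                break
            if join_n > 0:
                mean_join = join_sum / join_n
                if c < boundary_frac * mean_join:
                    break
                if size >= target_size and c < cohesion_frac * mean_join:
                    break
            labels[nxt] = cluster
            unassigned[nxt] = False
            n_left -= 1
            size += 1
            join_sum += c
            join_n += 1
            lo, hi = indptr[nxt], indptr[nxt + 1]
            conn[indices[lo:hi]] += data[lo:hi]
        cluster += 1
    return labels


# ---------------------------------------------------------------------------
# stage 3: resampled co-occurrence

@dataclass
class CoOccurrence:
    """Cell x cell co-clustering frequencies from resampled partitions.

    ``freq[i, j]`` = (#resamples where i and j co-clustered) /
    (#resamples containing both); entries with zero co-sampling are 0.
    Symmetric, values in [0, 1]; the diagonal is 1 wherever the cell was
    sampled at least once. Co-sampling counts are retained.
    """

    freq: np.ndarray
    cosampled: np.ndarray
    n_resamples: int

    def __post_init__(self) -> None:
        assert self.freq.shape == self.cosampled.shape


def resampled_cooccurrence(graph: sp.csr_matrix,
                           params: MetacellParams) -> CoOccurrence:
    """Partition ``n_resamples`` independent subsamples (without
    replacement, fraction ``resample_frac``) of the cell graph and
    accumulate co-clustering frequencies."""
    n = graph.shape[0]
    rng = _rng(params.seed, 12)
    m_sub = max(1, int(round(params.resample_frac * n)))
    R = params.n_resamples

    sampled = np.zeros((n, R), dtype=np.float32)
    memb_rows: list[np.ndarray] = []
    memb_cols: list[np.ndarray] = []
    col0 = 0
    for r in range(R):
        subset = (np.sort(rng.choice(n, size=m_sub, replace=False))
                  if m_sub < n else np.arange(n))
        labels = seed_and_grow(graph, subset, params.mc_target_size,
                               params.boundary_frac, params.cohesion_frac)
        sampled[subset, r] = 1.0
        memb_rows.append(subset)
        memb_cols.append(labels + col0)
        col0 += labels.max() + 1

    C = sp.csr_matrix(
        (np.ones(sum(len(x) for x in memb_rows), dtype=np.float32),
         (np.concatenate(memb_rows), np.concatenate(memb_cols))),
        shape=(n, col0),
    )
    co_clustered = np.asarray((C @ C.T).todense())
    co_sampled = sampled @ sampled.T
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(co_sampled > 0, co_clustered / co_sampled, 0.0)
    ever = sampled.any(axis=1)
    freq[np.diag_indices(n)] = np.where(ever, 1.0, 0.0)
    return CoOccurrence(freq.astype(np.float64),
                        co_sampled.astype(np.int64), R)


# ---------------------------------------------------------------------------
# stage 4: final partition

@dataclass
class MetacellPartition:
    """Per-cell metacell assignment (ids dense from 1; -1 = outlier)."""

    assignments: np.ndarray
    cell_index: pd.Index
    mc_coords: pd.DataFrame | None = field(default=None, repr=False)
    cell_coords: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ids = self.metacell_ids
        if len(ids) and not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("metacell ids must be dense from 1")

    @property
    def metacell_ids(self) -> np.ndarray:
        return np.unique(self.assignments[self.assignments != OUTLIER])

    @property
    def n_metacells(self) -> int:
        return len(self.metacell_ids)

    @property
    def sizes(self) -> pd.Series:
        a = self.assignments[self.assignments != OUTLIER]
        return pd.Series(a).value_counts().sort_index()

    @property
    def n_outliers(self) -> int:
        return int((self.assignments == OUTLIER).sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"metacell": self.assignments}, index=self.cell_index)
        if self.cell_coords is not None:
            df["x"] = self.cell_coords[:, 0]
            df["y"] = self.cell_coords[:, 1]
        return df


def final_partition(coc: CoOccurrence, params: MetacellParams,
                    cell_index: pd.Index | None = None,
                    on_all_outliers: str = "raise") -> MetacellPartition:
    """Final metacell cover of the co-occurrence matrix.

    A balanced kNN graph on co-occurrence values (K = ``k_coc``,
    in-degree cap ``alpha * k_coc``) is partitioned by seed-and-grow.
    Clusters below ``min_mc_size`` are dissolved: each of their cells
    joins the surviving metacell with maximal mean co-occurrence, or
    becomes an outlier when that mean is 0. With no surviving metacell
    the default is to raise ``AllOutliersError``; pass
    ``on_all_outliers='return'`` to get the all-outlier partition.
    """
    F = coc.freq
    n = F.shape[0]
    if cell_index is None:
        cell_index = pd.RangeIndex(n)
    k = min(params.k_coc, n - 1) if n > 1 else 1
    W = _balanced_knn(F, k, int(np.ceil(params.alpha * params.k_coc)))
    labels = seed_and_grow(W, np.arange(n), params.mc_target_size,
                           params.boundary_frac, params.cohesion_frac)

    sizes = np.bincount(labels)
    surviving = np.flatnonzero(sizes >= params.min_mc_size)
    if len(surviving) == 0:
        part = MetacellPartition(np.full(n, OUTLIER), cell_index)
        if on_all_outliers == "return":
            return part
        raise AllOutliersError(
            f"no cluster reached min_mc_size={params.min_mc_size}; "
            "all cells would be outliers"
        )

    assignments = np.full(n, OUTLIER, dtype=np.int64)
    members = {int(c): np.flatnonzero(labels == c) for c in surviving}
    for new_id, c in enumerate(sorted(members, key=lambda c: members[c].min()),
                               start=1):
        assignments[members[c]] = new_id
    mc_members = {mc: np.flatnonzero(assignments == mc)
                  for mc in range(1, len(surviving) + 1)}

    dissolved = np.flatnonzero(assignments == OUTLIER)
    if len(dissolved):
        # mean co-occurrence of each dissolved cell with each metacell
        means = np.stack(
            [F[np.ix_(dissolved, mem)].mean(axis=1)
             for mc, mem in sorted(mc_members.items())], axis=1
        )
        best = means.argmax(axis=1)
        best_val = means[np.arange(len(dissolved)), best]
        reassign = best_val > 0
        assignments[dissolved[reassign]] = best[reassign] + 1

    return MetacellPartition(assignments, cell_index)


# ---------------------------------------------------------------------------
# stage 5: 2D projection

def metacell_graph(partition: MetacellPartition, coc: CoOccurrence,
                   params: MetacellParams) -> "nx.Graph":
    """Module graph over metacells: top ``layout_knn`` inter-metacell
    mean co-occurrence links per metacell, greedily pruned (strongest
    first) so no metacell exceeds degree ``layout_max_degree``."""
    import networkx as nx

    ids = partition.metacell_ids
    M = len(ids)
    members = [np.flatnonzero(partition.assignments == mc) for mc in ids]
    link = np.zeros((M, M))
    for a in range(M):
        for b in range(a + 1, M):
            link[a, b] = link[b, a] = float(
                coc.freq[np.ix_(members[a], members[b])].mean()
            )
    G = nx.Graph()
    G.add_nodes_from(int(mc) for mc in ids)
    if M == 1:
        return G
    cand: set[tuple[int, int]] = set()
    for a in range(M):
        order = np.argsort(-link[a], kind="stable")
        for b in order[:params.layout_knn]:
            if b != a and link[a, b] > 0:
                cand.add((min(a, int(b)), max(a, int(b))))
    edges = sorted(cand, key=lambda e: (-link[e[0], e[1]], e))
    deg = np.zeros(M, dtype=int)
    for a, b in edges:
        if deg[a] < params.layout_max_degree and deg[b] < params.layout_max_degree:
            G.add_edge(int(ids[a]), int(ids[b]), weight=float(link[a, b]))
            deg[a] += 1
            deg[b] += 1
    return G


def project_2d(partition: MetacellPartition, coc: CoOccurrence,
               params: MetacellParams) -> MetacellPartition:
    """Force-directed layout of the metacell graph; each cell sits near
    its metacell, pulled toward linked metacells in proportion to its
    mean co-occurrence with them, with a small deterministic jitter.
    Outlier cells get NaN coordinates. Deterministic for a fixed seed."""
    import networkx as nx

    G = metacell_graph(partition, coc, params)
    ids = partition.metacell_ids
    if len(ids) == 1:
        pos = {int(ids[0]): np.zeros(2)}
    else:
        pos = nx.spring_layout(G, seed=int(params.seed) % (2 ** 32),
                               weight="weight")
    mc_xy = pd.DataFrame(
        {mc: pos[int(mc)] for mc in ids}, index=["x", "y"]
    ).T
    mc_xy.index.name = "metacell"

    n = len(partition.assignments)
    rng = _rng(params.seed, 13)
    jitter = rng.normal(scale=0.02, size=(n, 2))
    xy = np.full((n, 2), np.nan)
    members = {mc: np.flatnonzero(partition.assignments == mc) for mc in ids}
    for mc in ids:
        mem = members[mc]
        base = mc_xy.loc[mc, ["x", "y"]].to_numpy(dtype=float)
        acc = np.tile(base, (len(mem), 1))
        wsum = np.ones(len(mem))
        for nb in G.neighbors(int(mc)):
            w = coc.freq[np.ix_(mem, members[nb])].mean(axis=1) * 0.5
            acc += np.outer(w, mc_xy.loc[nb, ["x", "y"]].to_numpy(dtype=float))
            wsum += w
        xy[mem] = acc / wsum[:, None] + jitter[mem]
    return MetacellPartition(partition.assignments.copy(),
                             partition.cell_index, mc_xy, xy)


# ---------------------------------------------------------------------------
# model wrapper

class MetacellModel:
    """Metacell clustering model over a molecule-count matrix.

    Parameters
    ----------
    matrix : UmiMatrix
        Filtered molecule counts (cells already retained).
    params : MetacellParams, optional
        Clustering parameterization; defaults to the atlas settings.

    ``fit()`` runs feature selection, balanced kNN graph construction,
    resampled co-occurrence, the final partition and the 2D projection,
    and returns a :class:`MetacellResults`.
    """

    def __init__(self, matrix: UmiMatrix,
                 params: MetacellParams | None = None):
        self.matrix = matrix
        self.params = params or MetacellParams()
        self.params.validate()

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame,
                       params: MetacellParams | None = None) -> "MetacellModel":
        """Build from a dense cells x genes DataFrame (all features
        treated as genes)."""
        feats = pd.DataFrame({"kind": "gene"},
                             index=pd.Index(counts.columns, name="id"))
        cells = pd.DataFrame(index=pd.Index(counts.index, name="barcode"))
        cells["plate"] = 0
        cells["well"] = np.arange(len(cells))
        mat = UmiMatrix(sp.csr_matrix(counts.to_numpy()), cells, feats)
        mat.cells["total_umis"] = mat.host_totals()
        return cls(mat, params)

    def fit(self) -> "MetacellResults":
        p = self.params
        features = select_features(self.matrix, p)
        graph = build_balanced_knn(self.matrix, features, p)
        coc = resampled_cooccurrence(graph, p)
        part = final_partition(coc, p, cell_index=self.matrix.cells.index)
        part = project_2d(part, coc, p)
        return MetacellResults(self, features, graph, coc, part)


class MetacellResults:
    """Fitted metacell clustering: partition, co-occurrence, layout."""

    def __init__(self, model: MetacellModel, features: list[str],
                 graph: sp.csr_matrix, cooccurrence: CoOccurrence,
                 partition: MetacellPartition):
        self.model = model
        self.params = model.params
        self.features = features
        self.graph = graph
        self.cooccurrence = cooccurrence
        self.partition = partition

    @property
    def n_metacells(self) -> int:
        return self.partition.n_metacells

    @property
    def assignments(self) -> pd.Series:
        return pd.Series(self.partition.assignments,
                         index=self.partition.cell_index, name="metacell")

    def summary(self) -> str:
        p = self.params
        sizes = self.partition.sizes
        lines = [
            "Metacell clustering results",
            "===========================",
            f"cells:                 {len(self.partition.assignments)}",
            f"selected features:     {len(self.features)}",
            f"metacells:             {self.n_metacells}",
            f"outlier cells:         {self.partition.n_outliers}",
            f"metacell size range:   "
            f"{int(sizes.min()) if len(sizes) else 0}-"
            f"{int(sizes.max()) if len(sizes) else 0}",
            f"median metacell size:  "
            f"{float(sizes.median()) if len(sizes) else float('nan'):.1f}",
            "",
            f"k_graph={p.k_graph}  n_resamples={p.n_resamples}  "
            f"resample_frac={p.resample_frac}",
            f"k_coc={p.k_coc}  alpha={p.alpha}  min_mc_size={p.min_mc_size}  "
            f"seed={p.seed}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """2D projection: cells colored by metacell."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        xy = self.partition.cell_coords
        a = self.partition.assignments
        ok = a != OUTLIER
        ax.scatter(xy[ok, 0], xy[ok, 1], c=a[ok], cmap="tab20", s=6, lw=0)
        if self.partition.mc_coords is not None:
            for mc, row in self.partition.mc_coords.iterrows():
                ax.annotate(str(mc), (row["x"], row["y"]), fontsize=7)
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
        ax.set_title(f"{self.n_metacells} metacells")
        return ax
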