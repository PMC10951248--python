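"""UMI processing: molecule-count collapse, artifact filtering, retention.

Reads assigned to features are grouped per (cell, feature, UMI). Two
filters act before counting:

* an IVT-artifact filter removing UMIs whose read multiplicity is
  implausible under the run-level reads-per-UMI rate (one-sided binomial
  tail, Benjamini-Hochberg corrected, removed at q < 0.2). The exact
  statistic of the original plate-pipeline filter is not public; this
  binomial instantiation is flagged as such in the removal report and is
  pluggable behind ``FilterParams``.
* directional single-mismatch UMI collapse: UMI b is absorbed into UMI a
  when Hamming(a, b) = 1 and reads(a) >= ratio * reads(b) - 1 (ratio 2 by
  default), chains resolved by traversal from the highest-read UMI. The
  per-(cell, feature) molecule count is the number of surviving clusters.

Cell retention is strict (total host UMIs > 100); gene detection
(>= 10 total UMIs) is reported but never drops features — downstream
feature selection has its own rule.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .annotation import KIND_BACTERIAL, GeneInterval, features_to_frame
from .config import FilterParams
from .simulate import umi_codes_from_strings

HOST_KINDS = ("gene", "intergenic_bin")


@dataclass
class UmiMatrix:
    """Sparse cells x features molecule-count matrix with metadata.

    ``cells`` is indexed by barcode (columns: plate, well, total_umis —
    the host-feature total used for cell filtering); ``features`` is
    indexed by feature id (column: kind).
    """

    counts: sp.csr_matrix
    cells: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cells), len(self.features)):
            raise ValueError("counts shape does not match metadata")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative molecule counts")

    @property
    def host_feature_mask(self) -> np.ndarray:
        return self.features["kind"].isin(HOST_KINDS).to_numpy()

    def host_totals(self) -> np.ndarray:
        """Per-cell total molecules over host features (genes + bins)."""
        return np.asarray(
            self.counts[:, self.host_feature_mask].sum(axis=1)
        ).ravel()

    def subset_cells(self, mask: np.ndarray) -> "UmiMatrix":
        return UmiMatrix(
            sp.csr_matrix(self.counts[mask]),
            self.cells.loc[mask].copy(),
            self.features.copy(),
        )

    # -- IO ----------------------------------------------------------------
    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        mmwrite(str(prefix) + ".mtx", sp.coo_matrix(self.counts))
        self.cells.to_csv(str(prefix) + ".cells.tsv", sep="\t")
        self.features.to_csv(str(prefix) + ".features.tsv", sep="\t")

    @classmethod
    def read(cls, prefix: str | Path) -> "UmiMatrix":
        prefix = str(prefix)
        counts = sp.csr_matrix(mmread(prefix + ".mtx"))
        cells = pd.read_csv(prefix + ".cells.tsv", sep="\t", index_col=0)
        features = pd.read_csv(prefix + ".features.tsv", sep="\t", index_col=0)
        return cls(counts, cells, features)


def build_umi_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-(barcode, feature, UMI) read support from the assignment table.

    Only assigned reads contribute. Returns columns barcode, plate, well,
    feature_id, umi, reads, n_pos (distinct read positions).
    """
    ok = assignments[assignments["feature_id"].notna()]
    g = ok.groupby(["barcode", "plate", "well", "feature_id", "umi"],
                   sort=True, observed=True)
    out = g.agg(reads=("pos", "size"), n_pos=("pos", "nunique")).reset_index()
    return out


def filter_ivt_artifacts(umi_table: pd.DataFrame, params: FilterParams
                         ) -> tuple[pd.DataFrame, dict]:
    """Remove UMIs with implausibly high read multiplicity.

    Null: each of the run's R reads lands on one of its U observed UMIs
    uniformly, so a UMI's read count is Binomial(R, 1/U) with mean equal
    to the run-level reads-per-UMI rate. One-sided upper-tail p-values
    are BH-corrected; UMIs at q < ``params.umi_fdr_q`` are removed.
    """
    n_umis = len(umi_table)
    report = {
        "test": "binomial tail vs run-level reads-per-UMI rate "
                "(this pipeline's instantiation of the IVT-artifact filter)",
        "fdr_q": params.umi_fdr_q,
        "n_umis": int(n_umis),
        "n_removed": 0,
        "removed": [],
    }
    if n_umis == 0:
        return umi_table.copy(), report
    reads = umi_table["reads"].to_numpy()
    total_reads = int(reads.sum())
    report["reads_per_umi"] = total_reads / n_umis
    # p-values depend only on the read count: compute per unique value
    uniq, inv = np.unique(reads, return_inverse=True)
    pv_uniq = binom.sf(uniq - 1, total_reads, 1.0 / n_umis)
    pvals = pv_uniq[inv]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    drop = qvals < params.umi_fdr_q
    report["n_removed"] = int(drop.sum())
    removed = umi_table.loc[drop, ["barcode", "feature_id", "umi", "reads"]]
    removed = removed.assign(q_value=qvals[drop])
    report["removed"] = removed.to_dict("records")
    return umi_table.loc[~drop].reset_index(drop=True), report


def _directional_cluster_count(codes: np.ndarray, reads: np.ndarray,
                               umi_length: int, ratio: float) -> int:
    """Cluster count for one (cell, feature) group under directional
    adjacency, traversing from the highest-read UMI (ties by code)."""
    order = np.lexsort((codes, -reads))
    by_code = {int(c): i for i, c in enumerate(codes)}
    visited = np.zeros(len(codes), dtype=bool)
    n_clusters = 0
    for root in order:
        if visited[root]:
            continue
        n_clusters += 1
        stack = [root]
        visited[root] = True
        while stack:
            i = stack.pop()
            c = int(codes[i])
            for p in range(umi_length):
                shift = 2 * p
                cur = (c >> shift) & 3
                for b in range(4):
                    if b == cur:
                        continue
                    j = by_code.get(c ^ ((cur ^ b) << shift))
                    if j is None or visited[j]:
                        continue
                    if reads[i] >= ratio * reads[j] - 1:
                        visited[j] = True
                        stack.append(j)
    return n_clusters


def collapse_umis(umi_table: pd.DataFrame,
                  features: Sequence[GeneInterval] | pd.DataFrame,
                  params: FilterParams | None = None) -> UmiMatrix:
    """Collapse the UMI table into a molecule-count matrix.

    With collapse enabled, single-mismatch directional merging runs per
    (cell, feature) group; otherwise the count is the number of distinct
    UMIs. All UMIs must share one length. Collapse is idempotent at the
    matrix level: counts never exceed distinct-UMI counts and re-running
    on the surviving representatives changes nothing.
    """
    params = params or FilterParams()
    feat_df = (features_to_frame(features)
               if not isinstance(features, pd.DataFrame) else features.copy())
    feat_ids = feat_df["id"].to_numpy()
    feat_pos = {f: i for i, f in enumerate(feat_ids)}

    t = umi_table
    if len(t) == 0:
        raise ValueError("empty UMI table")
    umi_length = len(t["umi"].iloc[0])
    codes = umi_codes_from_strings(t["umi"].to_numpy(), umi_length)

    cell_key, cell_ids = pd.factorize(t["barcode"], sort=True)
    unknown = [f for f in t["feature_id"].unique() if f not in feat_pos]
    if unknown:
        raise ValueError(f"UMI table names unknown features: {unknown[:5]}")
    feat_key = t["feature_id"].map(feat_pos).to_numpy()
    group_key = cell_key.astype(np.int64) * len(feat_ids) + feat_key
    order = np.argsort(group_key, kind="stable")
    gk = group_key[order]
    codes_s = codes[order]
    reads_s = t["reads"].to_numpy()[order]

    # group boundaries
    starts = np.flatnonzero(np.concatenate(([True], gk[1:] != gk[:-1])))
    ends = np.append(starts[1:], len(gk))
    group_ids = gk[starts]
    sizes = ends - starts
    counts_out = sizes.astype(np.int64).copy()

    if params.collapse_enabled:
        # find groups containing at least one Hamming-1 pair: generate all
        # single-base neighbors and probe the (group, code) key space
        key_space = gk * np.int64(4 ** umi_length) + codes_s
        key_sorted = np.sort(key_space)
        multi = sizes > 1
        cand_rows = np.concatenate(
            [np.arange(s, e) for s, e in zip(starts[multi], ends[multi])]
        ) if multi.any() else np.empty(0, dtype=np.int64)
        affected = np.zeros(len(group_ids), dtype=bool)
        if len(cand_rows):
            c = codes_s[cand_rows]
            g = gk[cand_rows]
            hit = np.zeros(len(cand_rows), dtype=bool)
            for p in range(umi_length):
                shift = 2 * p
                cur = (c >> shift) & 3
                for d in (1, 2, 3):
                    nb = c ^ ((cur ^ ((cur + d) % 4)) << shift)
                    keys = g * np.int64(4 ** umi_length) + nb
                    i = np.searchsorted(key_sorted, keys)
                    ok = (i < len(key_sorted)) & (key_sorted[np.clip(i, 0, len(key_sorted) - 1)] == keys)
                    hit |= ok
            aff_groups = np.unique(g[hit])
            affected[np.searchsorted(group_ids, aff_groups)] = True
        for gi in np.flatnonzero(affected):
            s, e = starts[gi], ends[gi]
            counts_out[gi] = _directional_cluster_count(
                codes_s[s:e], reads_s[s:e], umi_length,
                params.umi_collapse_ratio,
            )

    row = (group_ids // len(feat_ids)).astype(np.int64)
    col = (group_ids % len(feat_ids)).astype(np.int64)
    counts = sp.csr_matrix(
        (counts_out, (row, col)), shape=(len(cell_ids), len(feat_ids)),
        dtype=np.int64,
    )

    meta = (t[["barcode", "plate", "well"]].drop_duplicates("barcode")
            .set_index("barcode").loc[cell_ids])
    cells = pd.DataFrame(index=pd.Index(cell_ids, name="barcode"))
    cells["plate"] = meta["plate"]
    cells["well"] = meta["well"]
    feat_out = feat_df.set_index("id")[["kind"]]
    m = UmiMatrix(counts, cells, feat_out)
    m.cells["total_umis"] = m.host_totals()
    return m


def filter_cells_genes(m: UmiMatrix, params: FilterParams
                       ) -> tuple[UmiMatrix, dict]:
    """Apply cell retention and gene-detection reporting.

    Cells whose host-feature total strictly exceeds ``min_cell_umis`` are
    retained. Genes (host features) with total UMIs >= the detection
    threshold are flagged detected in the feature table; no feature is
    dropped. Returns the retained matrix and a summary.
    """
    if m.counts.shape[0] == 0 or m.counts.shape[1] == 0:
        raise ValueError("empty matrix")
    totals = m.host_totals()
    keep = totals > params.min_cell_umis
    out = m.subset_cells(keep)
    gene_totals = np.asarray(out.counts.sum(axis=0)).ravel()
    host = out.host_feature_mask
    detected = host & (gene_totals >= params.min_gene_total_umis)
    out.features = out.features.copy()
    out.features["total_umis"] = gene_totals
    out.features["detected"] = detected
    retained_totals = out.cells["total_umis"].to_numpy()
    summary = {
        "n_cells_input": int(m.counts.shape[0]),
        "retained_cells": int(keep.sum()),
        "median_umis_per_retained_cell": float(np.median(retained_totals))
        if keep.any() else float("nan"),
        "detected_genes": int(detected.sum()),
        "min_cell_umis_strict": params.min_cell_umis,
        "min_gene_total_umis": params.min_gene_total_umis,
    }
    return out, summary


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2))
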