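"""Metacell QC, expression footprints, markers and composition.

A metacell's footprint is its pooled per-gene expression fraction; fold
enrichment is the regularized ratio of that fraction to the cross-
metacell median, (f_mc + eps) / (median_mc f + eps) with eps = 1e-5 by
default. Metacells lacking a specific signature (fewer than 50 genes at
fold-change >= 2) or with fewer than 10,000 pooled UMIs are filtered
(OR rule). Composition reports summarize retained cells over a
user-supplied metacell -> group map; group calls are never auto-derived.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import QcParams
from .metacell import OUTLIER, MetacellPartition
from .umi import UmiMatrix


@dataclass
class MetacellProfile:
    """Per-metacell pooled expression over host features.

    ``fractions`` rows sum to 1; ``fold_enrichment`` is strictly positive
    by regularization.
    """

    total_umis: pd.Series                # per metacell
    fractions: pd.DataFrame              # metacells x genes
    fold_enrichment: pd.DataFrame        # metacells x genes
    n_enriched_genes: pd.Series          # fold-change >= threshold
    fc_threshold: float
    epsilon: float


def compute_footprints(m: UmiMatrix, partition: MetacellPartition,
                       params: QcParams | None = None) -> MetacellProfile:
    """Pool counts per metacell and compute fold enrichments.

    Only host features (genes and rescued bins) enter the footprint.
    Raises if any metacell pools zero UMIs.
    """
    params = params or QcParams()
    params.validate()
    host = m.host_feature_mask
    counts = sp.csr_matrix(m.counts[:, host])
    genes = m.features.index[host]
    ids = partition.metacell_ids
    if len(ids) == 0:
        raise ValueError("partition has no metacells")

    pooled = np.zeros((len(ids), counts.shape[1]))
    for i, mc in enumerate(ids):
        mem = np.flatnonzero(partition.assignments == mc)
        pooled[i] = np.asarray(counts[mem].sum(axis=0)).ravel()
    totals = pooled.sum(axis=1)
    if (totals == 0).any():
        bad = ids[totals == 0].tolist()
        raise ValueError(f"metacells with zero UMIs: {bad}")

    frac = pooled / totals[:, None]
    med = np.median(frac, axis=0)
    eps = params.epsilon
    fold = (frac + eps) / (med + eps)
    idx = pd.Index(ids, name="metacell")
    fold_df = pd.DataFrame(fold, index=idx, columns=genes)
    n_enr = (fold_df >= params.fc_threshold).sum(axis=1)
    return MetacellProfile(
        total_umis=pd.Series(totals, index=idx, name="total_umis"),
        fractions=pd.DataFrame(frac, index=idx, columns=genes),
        fold_enrichment=fold_df,
        n_enriched_genes=n_enr.rename("n_enriched_genes"),
        fc_threshold=params.fc_threshold,
        epsilon=eps,
    )


def filter_metacells(profile: MetacellProfile,
                     partition: MetacellPartition,
                     params: QcParams | None = None
                     ) -> tuple[list[int], list[int], dict]:
    """Drop weak metacells: fewer than ``min_enriched_genes`` enriched
    genes OR total UMIs below ``min_mc_total_umis``.

    Returns (kept ids, dropped ids, report) where the report counts the
    dropped metacells and the single cells they represent.
    """
    params = params or QcParams()
    params.validate()
    weak_sig = profile.n_enriched_genes < params.min_enriched_genes
    low_umi = profile.total_umis < params.min_mc_total_umis
    dropped = profile.total_umis.index[weak_sig | low_umi].tolist()
    kept = profile.total_umis.index[~(weak_sig | low_umi)].tolist()
    dropped_cells = int(np.isin(partition.assignments, dropped).sum())
    report = {
        "n_metacells_input": int(len(profile.total_umis)),
        "n_dropped": len(dropped),
        "dropped_metacells": [int(x) for x in dropped],
        "n_dropped_cells": dropped_cells,
        "rule": (f"n_enriched_genes < {params.min_enriched_genes} "
                 f"(fc >= {params.fc_threshold}) OR "
                 f"total_umis < {params.min_mc_total_umis}"),
    }
    return kept, dropped, report


def composition_report(partition: MetacellPartition,
                       groups: dict[str, list[int]]) -> pd.Series:
    """Fraction of retained (non-outlier) cells per named group.

    ``groups`` maps group name -> metacell ids; a metacell mapped to two
    groups is an error. Cells in unmapped metacells are reported under
    'unassigned'; fractions (groups + unassigned) sum to 1.
    """
    seen: dict[int, str] = {}
    for name, mcs in groups.items():
        for mc in mcs:
            if mc in seen:
                raise ValueError(
                    f"metacell {mc} mapped to both {seen[mc]!r} and {name!r}"
                )
            seen[mc] = name
    a = partition.assignments
    retained = a[a != OUTLIER]
    n = len(retained)
    if n == 0:
        raise ValueError("no retained cells")
    fracs = {}
    for name, mcs in groups.items():
        fracs[name] = float(np.isin(retained, mcs).sum()) / n
    fracs["unassigned"] = 1.0 - float(
        np.isin(retained, list(seen)).sum()
    ) / n
    return pd.Series(fracs, name="fraction")


def top_markers(profile: MetacellProfile, n: int) -> pd.DataFrame:
    """Top-n marker genes per metacell by fold enrichment.

    Ties break by total pooled UMIs (descending) then gene id; rows per
    metacell = min(n, #genes). Suitable as an in-situ probe shortlist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gene_tot = (profile.fractions * profile.total_umis.to_numpy()[:, None]).sum(
        axis=0
    )
    rows = []
    for mc in profile.fold_enrichment.index:
        fe = profile.fold_enrichment.loc[mc]
        tab = pd.DataFrame(
            {"gene": fe.index, "fold_enrichment": fe.to_numpy(),
             "total_umis": gene_tot.reindex(fe.index).to_numpy()}
        )
        tab = tab.sort_values(
            ["fold_enrichment", "total_umis", "gene"],
            ascending=[False, False, True], kind="stable",
        ).head(n)
        tab.insert(0, "metacell", mc)
        tab.insert(1, "rank", np.arange(1, len(tab) + 1))
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)
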