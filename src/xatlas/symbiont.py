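"""Per-cell endosymbiont quantification and infection classification.

The two bacterial genomes (one Chlamydia-related, one related to
Gammaproteobacteria) are counted as whole-genome single features on both
strands: polyA capture of bacterial transcripts is inefficient, so
aggregate genome-wide molecule counts serve as a per-cell presence
proxy. Reads whose mapping is not unique in the combined host+bacteria
reference are dropped as ambiguous and logged. Bacterial UMIs collapse
with the same directional rule as host UMIs, keyed genome-wide.

Signals are pooled per metacell with a dual normalization — each
bacterium's share of total bacterial molecules, and its rate per host
molecule (correcting per-cell sampling efficiency) — and classified per
cell at a configurable UMI threshold (the per-cell cutoff is this
package's reporting convention; every report carries it, and per-animal
infected percentages are given as a threshold sweep).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FilterParams, SymbiontParams
from .metacell import OUTLIER, MetacellPartition
from .umi import UmiMatrix, build_umi_table, collapse_umis

STATE_NONE = "none"
STATE_A = "A"
STATE_B = "B"
STATE_BOTH = "both"


@dataclass
class SymbiontProfile:
    """Per-cell symbiont molecule counts plus host totals.

    ``cells`` is indexed by barcode with columns count_a, count_b,
    host_umis and (after classification) state.
    """

    cells: pd.DataFrame
    bacterial_ids: tuple[str, str]
    n_ambiguous_reads: int


def count_symbiont_umis(assignments: pd.DataFrame,
                        bacterial_ids: tuple[str, str],
                        matrix: UmiMatrix,
                        params: FilterParams | None = None
                        ) -> SymbiontProfile:
    """Per-cell UMI-collapsed molecule counts for each bacterium.

    ``assignments`` is the read->feature table; reads on either bacterial
    genome with ``unique_flag`` False are ambiguous between references
    and dropped (their number is logged in the profile). ``matrix``
    supplies each cell's host UMI total. Cells present in the matrix but
    without bacterial reads report zero counts.
    """
    params = params or FilterParams()
    id_a, id_b = bacterial_ids
    # the combined reference (matrix features + assigned chromosomes)
    # defines the valid bacterial ids
    known = (set(matrix.features.index)
             | set(assignments["feature_id"].dropna().unique())
             | set(assignments["chrom"].unique()))
    for b in bacterial_ids:
        if b not in known:
            raise ValueError(f"unknown bacterial feature id: {b}")

    bac = assignments[assignments["feature_id"].isin(bacterial_ids)]
    ambiguous = int((~bac["unique_flag"].astype(bool)).sum())
    bac = bac[bac["unique_flag"].astype(bool)]

    out = pd.DataFrame(index=matrix.cells.index.copy())
    out["count_a"] = 0
    out["count_b"] = 0
    out["host_umis"] = matrix.cells["total_umis"]

    if len(bac):
        table = build_umi_table(bac)
        feats = pd.DataFrame({"id": list(bacterial_ids),
                              "kind": ["bacterial_genome"] * 2})
        sub = collapse_umis(table, feats, params)
        counts = pd.DataFrame(
            np.asarray(sub.counts.todense()),
            index=sub.cells.index, columns=sub.features.index,
        )
        common = counts.index.intersection(out.index)
        out.loc[common, "count_a"] = counts.loc[common, id_a].astype(np.int64)
        out.loc[common, "count_b"] = counts.loc[common, id_b].astype(np.int64)
    return SymbiontProfile(out, bacterial_ids, ambiguous)


def normalize_signals(profile: SymbiontProfile,
                      partition: MetacellPartition) -> pd.DataFrame:
    """Pool counts per metacell and normalize two ways per bacterium:

    * share   = pooled counts_b / pooled total bacterial counts
      (0 by convention in metacells without bacterial molecules);
    * rate    = pooled counts_b / pooled host UMIs.
    """
    cells = profile.cells
    a = pd.Series(partition.assignments,
                  index=partition.cell_index, name="metacell")
    df = cells.join(a, how="inner")
    df = df[df["metacell"] != OUTLIER]
    g = df.groupby("metacell")[["count_a", "count_b", "host_umis"]].sum()
    tot_bac = g["count_a"] + g["count_b"]
    with np.errstate(invalid="ignore", divide="ignore"):
        share_a = np.where(tot_bac > 0, g["count_a"] / tot_bac, 0.0)
        share_b = np.where(tot_bac > 0, g["count_b"] / tot_bac, 0.0)
    out = pd.DataFrame(
        {
            "pooled_a": g["count_a"],
            "pooled_b": g["count_b"],
            "pooled_host": g["host_umis"],
            "share_a": share_a,
            "share_b": share_b,
            "rate_a": g["count_a"] / g["host_umis"],
            "rate_b": g["count_b"] / g["host_umis"],
        },
        index=g.index,
    )
    return out


def classify_infection(profile: SymbiontProfile,
                       animals: pd.Series,
                       params: SymbiontParams | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Per-cell infection state and per-animal summary.

    State is 'both' when both counts reach the threshold, 'A'/'B' when
    only one does, else 'none'. Cells lacking an animal id are excluded
    with a warning entry in the summary. The per-animal report gives the
    percentage of infected cells at the calling threshold plus a sweep
    over ``params.sweep_thresholds`` and each bacterium's contribution.
    """
    params = params or SymbiontParams()
    params.validate()
    t = params.min_symbiont_umis
    cells = profile.cells.copy()
    a_pos = cells["count_a"] >= t
    b_pos = cells["count_b"] >= t
    state = np.where(a_pos & b_pos, STATE_BOTH,
                     np.where(a_pos, STATE_A,
                              np.where(b_pos, STATE_B, STATE_NONE)))
    cells["state"] = state

    animals = animals.reindex(cells.index)
    missing = int(animals.isna().sum())
    cells["animal"] = animals

    known = cells[cells["animal"].notna()].copy()
    known["animal"] = known["animal"].astype(int)
    per_animal = {}
    for animal, grp in known.groupby("animal"):
        n = len(grp)
        inf = grp["state"] != STATE_NONE
        per_animal[int(animal)] = {
            "n_cells": int(n),
            "pct_infected": 100.0 * float(inf.sum()) / n,
            "pct_a": 100.0 * float((grp["state"].isin([STATE_A, STATE_BOTH])).sum()) / n,
            "pct_b": 100.0 * float((grp["state"].isin([STATE_B, STATE_BOTH])).sum()) / n,
            "pct_both": 100.0 * float((grp["state"] == STATE_BOTH).sum()) / n,
            "pct_infected_by_threshold": {
                int(th): 100.0 * float(
                    ((grp["count_a"] >= th) | (grp["count_b"] >= th)).sum()
                ) / n
                for th in params.sweep_thresholds
            },
        }
    summary = {
        "threshold_umis": int(t),
        "n_cells": int(len(cells)),
        "n_cells_missing_animal": missing,
        "n_ambiguous_reads_dropped": int(profile.n_ambiguous_reads),
        "per_animal": per_animal,
    }
    return cells, summary
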