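"""Shared fixtures: one small synthetic experiment processed end-to-end."""
from __future__ import annotations

from types import SimpleNamespace

import pytest

import xatlas as xa


def tiny_config(seed: int = 11, **overrides) -> xa.SimulationConfig:
    kw = dict(
        n_plates=1,
        n_genes=120,
        n_cell_types=4,
        genes_per_type_marker=5,
        depth_median=150.0,
        seed=seed,
    )
    kw.update(overrides)
    return xa.SimulationConfig(**kw)


@pytest.fixture(scope="session")
def tiny_run():
    """One plate (380 cells, 4 types) simulated and processed through
    annotation, assignment and counting."""
    config = tiny_config()
    ann = xa.simulate_annotation(config)
    reads, truth = xa.simulate_reads(config, ann)
    extended = xa.extend_intervals(ann.features, ann.chrom_sizes)
    bins = xa.build_intergenic_bins(extended, ann.chrom_sizes, reads)
    features = extended + bins
    assignments = xa.assign_reads(reads, features)
    table = xa.build_umi_table(assignments)
    filt = xa.FilterParams()
    table_f, ivt_report = xa.filter_ivt_artifacts(table, filt)
    matrix = xa.collapse_umis(table_f, features, filt)
    retained, summary = xa.filter_cells_genes(matrix, filt)
    return SimpleNamespace(
        config=config, ann=ann, reads=reads, truth=truth,
        extended=extended, bins=bins, features=features,
        assignments=assignments, umi_table=table, ivt_report=ivt_report,
        matrix=matrix, retained=retained, summary=summary, filter=filt,
    )


@pytest.fixture(scope="session")
def clustered_run():
    """Two plates, four well-separated types, clustered into metacells."""
    config = tiny_config(seed=5, n_plates=2, n_genes=200,
                         genes_per_type_marker=8, depth_median=300.0)
    ann = xa.simulate_annotation(config)
    reads, truth = xa.simulate_reads(config, ann)
    extended = xa.extend_intervals(ann.features, ann.chrom_sizes)
    bins = xa.build_intergenic_bins(extended, ann.chrom_sizes, reads)
    features = extended + bins
    assignments = xa.assign_reads(reads, features)
    table, _ = xa.filter_ivt_artifacts(
        xa.build_umi_table(assignments), xa.FilterParams()
    )
    matrix = xa.collapse_umis(table, features, xa.FilterParams())
    retained, _ = xa.filter_cells_genes(matrix, xa.FilterParams())
    params = xa.MetacellParams(k_graph=50, n_resamples=200,
                               mc_target_size=80, seed=5)
    results = xa.MetacellModel(retained, params).fit()
    return SimpleNamespace(
        config=config, truth=truth, assignments=assignments,
        retained=retained, params=params, results=results,
    )
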