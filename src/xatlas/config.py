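"""Run configuration: parameter blocks for every pipeline stage.

Every stochastic stage draws from a single run seed; parameter blocks
round-trip losslessly through YAML so a run is fully described by its
config file.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SimulationConfig",
    "FilterParams",
    "MetacellParams",
    "QcParams",
    "SymbiontParams",
    "RunConfig",
]


def _default_type_proportions(n_types: int) -> tuple[float, ...]:
    """Cell-type mixing proportions for the synthetic organism.

    The first six types mirror the abundance ranking of a small worm's
    tissues (gut 30%, epidermis 22%, muscle 8%, ciliated 7%, neurons 5%,
    pigmented 5%); any remaining types split the leftover mass evenly.
    """
    base = [0.30, 0.22, 0.08, 0.07, 0.05, 0.05]
    if n_types <= len(base):
        p = base[:n_types]
        s = sum(p)
        return tuple(x / s for x in p)
    rest = 1.0 - sum(base)
    extra = n_types - len(base)
    return tuple(base + [rest / extra] * extra)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic MARS-seq experiment.

    The generator emulates plate-based 3'-biased scRNA-seq: 384-well
    capture plates with 4 empty control wells each, log-normal per-cell
    UMI depth with a median of a few hundred molecules, cell-type marker
    programs, reads piling near (and past) annotated 3' ends, and two
    intracellular bacteria planted in subsets of cell types.
    """

    n_plates: int = 6
    wells_per_plate: int = 384
    empty_wells_per_plate: int = 4
    n_animals: int = 4
    n_cell_types: int = 8
    type_proportions: tuple[float, ...] | None = None
    n_genes: int = 600
    genes_per_type_marker: int = 10
    marker_fold: float = 10.0
    n_hidden_genes: int = 5
    hidden_gene_weight: float = 4.0
    n_chromosomes: int = 4
    # depth model: log-normal with the given median and log-sd
    depth_median: float = 400.0
    depth_sigma: float = 0.6
    reads_per_umi: float = 2.0
    # 3' bias: this fraction of a gene's reads falls within bias_window_bp
    # of the transcript 3' end (which may lie past the annotated end)
    bias_3prime: float = 0.7
    bias_window_bp: int = 1000
    max_utr_overhang_bp: int = 800
    umi_length: int = 8
    umi_error_rate: float = 0.005
    nonunique_rate: float = 0.03
    # infection model: per-cell-type Bernoulli probabilities per symbiont
    infection_prob_a: dict[int, float] = field(
        default_factory=lambda: {0: 0.10, 1: 0.10}
    )
    infection_prob_b: dict[int, float] = field(default_factory=lambda: {0: 0.20})
    symbiont_load_median: float = 20.0
    symbiont_load_sigma: float = 1.5
    ambient_rate: float = 0.05
    ambient_host_rate: float = 5.0
    animal_infection_scale: tuple[float, ...] = (1.0, 1.0, 1.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type_proportions is None:
            self.type_proportions = _default_type_proportions(self.n_cell_types)
        else:
            self.type_proportions = tuple(self.type_proportions)
        self.validate()

    def validate(self) -> None:
        if self.wells_per_plate <= self.empty_wells_per_plate:
            raise ValueError("wells_per_plate must exceed empty_wells_per_plate")
        if self.n_genes < self.n_cell_types * self.genes_per_type_marker:
            raise ValueError(
                "n_genes must be >= n_cell_types * genes_per_type_marker"
            )
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        for p in (self.bias_3prime, self.umi_error_rate, self.nonunique_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p!r} outside [0, 1]")
        for m in (self.infection_prob_a, self.infection_prob_b):
            for t, p in m.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"infection probability {p!r} outside [0, 1]")
                if not 0 <= int(t) < self.n_cell_types:
                    raise ValueError(f"infection model names unknown cell type {t}")
        assert self.type_proportions is not None
        if len(self.type_proportions) != self.n_cell_types:
            raise ValueError("type_proportions length must equal n_cell_types")
        if abs(sum(self.type_proportions) - 1.0) > 1e-6:
            raise ValueError("type_proportions must sum to 1")

    @property
    def cells_per_plate(self) -> int:
        return self.wells_per_plate - self.empty_wells_per_plate

    @property
    def n_cells(self) -> int:
        return self.n_plates * self.cells_per_plate


@dataclass
class FilterParams:
    """UMI-processing thresholds.

    ``min_cell_umis`` is a strict lower bound (cells are retained when
    their host-feature total exceeds it); ``min_gene_total_umis`` is an
    inclusive detection threshold used for reporting only.
    """

    min_cell_umis: int = 100
    min_gene_total_umis: int = 10
    umi_fdr_q: float = 0.2
    umi_collapse_ratio: float = 2.0
    collapse_enabled: bool = True

    def validate(self) -> None:
        for v in (self.min_cell_umis, self.min_gene_total_umis, self.umi_fdr_q):
            if v < 0:
                raise ValueError("filter thresholds must be >= 0")


@dataclass
class MetacellParams:
    """Metacell clustering parameterization.

    Defaults follow the atlas parameterization: feature selection at a
    depth-scaling correlation threshold of -0.05 and >100 total molecules,
    a balanced kNN graph with K=150, 1,000 partitions resampling 75% of
    the cells, a final co-occurrence partition with K=30, alpha=2 and
    min_mc_size=30, and a 2D layout with kNN=20 and module graph degree
    capped at 4.
    """

    szcor_threshold: float = -0.05
    szcor_select_above: bool = True
    min_feature_umis: int = 100  # strict >
    k_graph: int = 150
    n_resamples: int = 1000
    resample_frac: float = 0.75
    k_coc: int = 30
    alpha: float = 2.0
    min_mc_size: int = 30
    layout_knn: int = 20
    layout_max_degree: int = 4
    mc_target_size: int = 100
    # seed-and-grow natural-boundary rule: stop when the best candidate's
    # connectivity falls below boundary_frac of the mean join connectivity;
    # grow past the target only while it stays above cohesion_frac of it
    boundary_frac: float = 0.25
    cohesion_frac: float = 0.5
    downsample_quantile: float = 0.05
    downsample_cap: int = 750
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.resample_frac <= 1.0:
            raise ValueError("resample_frac must be in (0, 1]")
        for k in (self.k_graph, self.k_coc, self.layout_knn):
            if k < 1:
                raise ValueError("k parameters must be >= 1")
        if self.min_mc_size < 1:
            raise ValueError("min_mc_size must be >= 1")
        if self.mc_target_size < 1:
            raise ValueError("mc_target_size must be >= 1")


@dataclass
class QcParams:
    """Metacell QC thresholds: a metacell is dropped when it has fewer
    than ``min_enriched_genes`` genes at fold-change >= ``fc_threshold``
    OR fewer than ``min_mc_total_umis`` pooled UMIs."""

    min_enriched_genes: int = 50
    fc_threshold: float = 2.0
    min_mc_total_umis: int = 10000
    epsilon: float = 1e-5

    def validate(self) -> None:
        for v in (self.min_enriched_genes, self.fc_threshold,
                  self.min_mc_total_umis, self.epsilon):
            if v <= 0:
                raise ValueError("QC parameters must be positive")


@dataclass
class SymbiontParams:
    """Per-cell infection-call threshold on collapsed bacterial UMIs.

    The per-cell cutoff is this package's own reporting convention (the
    underlying signal is quantified per metacell and per animal); every
    report carries the threshold used.
    """

    min_symbiont_umis: int = 2
    sweep_thresholds: tuple[int, ...] = (1, 2, 3, 4, 5)

    def validate(self) -> None:
        if self.min_symbiont_umis < 1:
            raise ValueError("min_symbiont_umis must be >= 1")


@dataclass
class RunConfig:
    """Top-level run configuration: one global seed plus per-stage blocks
    and an optional metacell-group map for composition reports."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterParams = field(default_factory=FilterParams)
    metacell: MetacellParams = field(default_factory=MetacellParams)
    qc: QcParams = field(default_factory=QcParams)
    symbiont: SymbiontParams = field(default_factory=SymbiontParams)
    groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # the run seed governs every stochastic stage
        self.simulation.seed = self.seed
        self.metacell.seed = self.seed

    def validate(self) -> None:
        self.simulation.validate()
        self.filter.validate()
        self.metacell.validate()
        self.qc.validate()
        self.symbiont.validate()

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # YAML-friendly containers
        d["simulation"]["type_proportions"] = list(
            self.simulation.type_proportions or ()
        )
        d["simulation"]["animal_infection_scale"] = list(
            self.simulation.animal_infection_scale
        )
        d["symbiont"]["sweep_thresholds"] = list(self.symbiont.sweep_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        sim = dict(d.get("simulation", {}))
        for key in ("infection_prob_a", "infection_prob_b"):
            if key in sim:
                sim[key] = {int(k): float(v) for k, v in sim[key].items()}
        if sim.get("type_proportions") is not None:
            sim["type_proportions"] = tuple(sim["type_proportions"])
        if "animal_infection_scale" in sim:
            sim["animal_infection_scale"] = tuple(sim["animal_infection_scale"])
        sym = dict(d.get("symbiont", {}))
        if "sweep_thresholds" in sym:
            sym["sweep_thresholds"] = tuple(sym["sweep_thresholds"])
        cfg = cls(
            seed=int(d.get("seed", 0)),
            simulation=SimulationConfig(**sim),
            filter=FilterParams(**d.get("filter", {})),
            metacell=MetacellParams(**d.get("metacell", {})),
            qc=QcParams(**d.get("qc", {})),
            symbiont=SymbiontParams(**d.get("symbiont", {})),
            groups={str(k): [int(x) for x in v]
                    for k, v in d.get("groups", {}).items()},
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
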