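# Methods

This note documents the models and procedures implemented in `xatlas`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Annotation repair

3′-biased, polyA-primed protocols read out the 3′ end of transcripts.
When 3′ UTRs are under-annotated, a large fraction of reads maps just
downstream of annotated gene ends. Two repairs run before counting:

* **Interval extension.** Each gene's 3′ end is moved downstream
  (strand-relative) by `min(1000 bp, gap to the next same-strand gene,
  distance to the chromosome end)`. The 5′ boundary never moves.
  Extended intervals record the pre-extension 3′ coordinate, which makes
  the operation idempotent. Same-strand overlaps in the input are an
  error naming the offending pair; opposite-strand overlaps are allowed,
  since the rule is per strand.
* **Intergenic bin rescue.** Chromosomes are tiled with 2,000-bp bins;
  bins overlapping any extended gene (either strand) are discarded, and
  bins with ≥ 100 uniquely mapping reads (both strands; multi-mappers
  excluded) become `intergenic_bin` features. The threshold is applied
  to all uniquely mapping reads, before cell filtering.

Coordinates are 0-based half-open throughout; GFF input is converted on
read. Read assignment gives priority to a strand-matched gene, then a
bacterial genome (whole chromosome, both strands), then a strand-
agnostic bin; residual ties would break by nearest 3′ end then feature
id, though with non-overlapping same-strand features they do not arise.
Unassigned reads carry a reason code (`intergenic`,
`unknown_chromosome`) and unknown chromosomes are never fatal.

## UMI processing

**IVT-artifact filter.** Linear amplification occasionally produces UMIs
with implausibly many reads. The null model here: each of the run's R
reads lands uniformly on one of its U observed UMIs, so a UMI's read
count is Binomial(R, 1/U) with mean equal to the run-level reads-per-UMI
rate. One-sided upper-tail p-values are Benjamini–Hochberg corrected and
UMIs at q < 0.2 are removed. The exact statistic used by the original
plate-pipeline software is not public; this binomial instantiation is
our own, is flagged as such in the removal report, and sits behind
`FilterParams` so it can be swapped. Because true reads-per-UMI
distributions are heavier-tailed than binomial, the filter removes a
small percentage of genuine high-read UMIs at q < 0.2; this is the
intended permissiveness of the threshold, and the count effect is
negligible (well under 1% of molecules).

**Directional UMI collapse.** Within each (cell, feature) group, UMI *b*
is absorbed into *a* when Hamming(a, b) = 1 and
reads(a) ≥ `ratio`·reads(b) − 1 (ratio 2), with chains resolved by
traversal from the highest-read UMI (ties by sequence). The molecule
count is the number of surviving clusters. This is the standard
directional-adjacency network used in UMI deduplication practice;
`collapse_enabled=False` counts distinct UMIs instead. Implementation
note: candidate Hamming-1 pairs are found by probing all single-base
neighbors in a hashed (group, UMI) key space, so groups without
neighbors — the overwhelming majority — never enter the per-group
traversal.

**Retention.** Cells are retained when their total over host features
(genes + bins, excluding bacterial genomes) strictly exceeds 100
molecules. Gene "detection" (≥ 10 total molecules) is reported but never
drops features; downstream feature selection has its own rule. Both
thresholds are configurable.

## Metacell clustering

The clustering model groups cells into metacells — small,
transcriptionally homogeneous clusters — and is exposed as
`MetacellModel(matrix, params).fit() -> MetacellResults`.

* **Feature selection.** Host features with > 100 total molecules whose
  depth-scaling correlation (Pearson correlation between down-sampled
  counts and log total depth) is ≥ −0.05. The direction of the threshold
  was an open choice; the default treats features strongly
  *anticorrelated* with depth as artifacts and keeps the rest, with
  `szcor_select_above=False` flipping the rule. Rescued intergenic bins
  enter the pool exactly like genes. Features are returned in decreasing
  variance/mean order for a deterministic ranking.
* **Balanced kNN graph.** Similarity is the Pearson correlation of
  log2(1 + down-sampled counts); the down-sampling depth is the 5th
  percentile of per-cell totals capped at 750. Each cell keeps its
  K = 150 best neighbors (rank weights (K − r)/K); targets above an
  in-degree of 3K shed their worst-ranked incoming edges, so hubs cannot
  dominate. With fewer than K + 1 cells, K is reduced with a warning.
* **Seed-and-grow cover.** Partitions are produced by seeded growth: the
  unassigned cell with maximal weighted degree seeds a cluster, which
  repeatedly absorbs the unassigned cell with the strongest total
  connection to it. Growth aims at `mc_target_size` (default 100 cells,
  chosen to match typical metacell sizes of one to a few hundred cells)
  but respects natural community boundaries: it always stops when the
  best candidate's connection falls below `boundary_frac` (0.25) of the
  mean connection at which earlier members joined, and continues past
  the target only while the candidate stays above `cohesion_frac` (0.5)
  of that mean. A tight community larger than the target is therefore
  kept whole, while diffuse growth stops at the target. Ties break by
  cell id everywhere, making the cover deterministic.
* **Co-occurrence.** 1,000 independent 75% subsamples (without
  replacement) are each partitioned; entry (i, j) of the co-occurrence
  matrix is the fraction of resamples containing both cells in which
  they co-clustered. Co-sampling counts are retained; the diagonal is 1
  wherever a cell was ever sampled.
* **Final partition.** A balanced kNN graph on co-occurrence values
  (K = 30, in-degree cap α·K with α = 2 — α interpreted as the balancing
  multiplier) is covered by the same seed-and-grow procedure. Clusters
  below min_mc_size = 30 are dissolved; their cells join the surviving
  metacell with maximal mean co-occurrence or become outliers when that
  mean is 0. Metacell ids are dense from 1; an all-outlier result raises
  by default (`on_all_outliers="return"` yields the partition instead).
* **2D projection.** A module graph over metacells takes each
  metacell's top-20 inter-metacell mean co-occurrence links and prunes,
  strongest first, to maximum degree 4; `networkx.spring_layout` (seeded)
  places metacells, and each cell sits at its metacell's position pulled
  toward linked metacells in proportion to its mean co-occurrence with
  them, plus a small deterministic jitter. Outliers get NaN coordinates.

All randomness flows from the single run seed through named
`numpy.random.default_rng([seed, stream])` streams, so two runs with the
same seed are byte-identical.

## Metacell QC, markers, composition

Fold enrichment is (metacell gene fraction + ε) / (cross-metacell median
fraction + ε) with ε = 1e−5; the regularizer keeps enrichments finite
for genes absent from most metacells and its exact value only matters
for very lowly expressed genes. A metacell is dropped when it has fewer
than 50 genes at fold-change ≥ 2 **or** fewer than 10,000 pooled UMIs
(OR rule). Composition reports require an explicit metacell → group map;
group calls are never auto-derived, and unmapped cells are reported as
`unassigned` so fractions always sum to 1. Marker tables rank genes per
metacell by fold enrichment with ties broken by total UMIs then id.

## Endosymbiont quantification

Bacterial transcripts are not polyadenylated, so polyA capture detects
them inefficiently; aggregate genome-wide counts are therefore used as a
per-cell presence proxy rather than per-gene expression. Each bacterial
genome is a single whole-chromosome feature counted on both strands.
Reads not uniquely mapped in the combined host + bacteria reference are
dropped as ambiguous and logged. Bacterial UMIs collapse with the same
directional rule as host UMIs.

Per metacell, two normalizations are reported per bacterium: its share
of pooled bacterial molecules, and its rate per pooled host molecule
(correcting for per-cell sampling efficiency). Metacells without
bacterial molecules report share 0 by convention.

The per-cell infection call (state ∈ {none, A, B, both}) uses a
configurable UMI threshold, default ≥ 2 collapsed UMIs — a reporting
convention of this package, since the underlying signal is quantified
per metacell and per animal rather than per cell. Every report carries
the threshold, and per-animal infected percentages are additionally
reported as a sweep over thresholds 1–5 so the dependence on the cutoff
is visible.

## Synthetic experiment generator

The generator emulates the statistical structure the pipeline assumes:

* 384-well capture plates with 4 empty control wells per plate; empty
  wells emit only ambient molecules (Poisson, ~5 host molecules per
  well) and serve as true negatives for the cell filter;
* per-cell molecule depth log-normal with median 400 and log-sd 0.6
  (median of a few hundred, matching shallow plate-based data);
* cell types drawn from proportions mirroring a small worm's tissue
  ranking (gut 0.30, epidermis 0.22, muscle 0.08, ciliated 0.07,
  neurons 0.05, pigmented 0.05, remainder split evenly), each with a
  disjoint 10-gene marker program at 10-fold over baseline;
* reads per molecule geometric with mean 2; 70% of a gene's reads fall
  within 1 kb of the transcript 3′ end, and each gene carries an
  unannotated 3′ UTR overhang (uniform up to 800 bp, bounded by its
  downstream neighbor) so interval extension has real signal to recover;
* five hidden (unannotated) genes placed in intergenic 2-kb windows,
  exercising bin rescue;
* UMIs are 8-mers, distinct within each (cell, feature) group at
  generation so planted molecule counts are exact in the zero-error
  regime; each read mutates one UMI base with probability 0.005;
* two bacteria as separate non-host chromosomes: a Chlamydia-like
  symbiont infecting gut and epidermis at probability 0.10 each, and a
  Gammaproteobacteria-like symbiont restricted to gut at 0.20, with
  per-infected-cell loads log-normal (median 20, log-sd 1.5), ambient
  contamination at 0.05 expected molecules per uninfected cell, and the
  fourth animal's infection probabilities scaled by 0.5 (three animals
  end up near 10% infected cells, the fourth near 5%);
* 3% of reads flagged non-unique (excluded from bin rescue and, on
  bacterial genomes, dropped as ambiguous).

What the generator does **not** emulate: base-level sequencing error
beyond single-mismatch UMI perturbation, doublets, ambient host RNA in
cell-bearing wells, batch effects between plates, spliced alignment, or
continuous (non-discrete) expression topologies. Passing tests therefore
demonstrate correctness of the algorithms and recoverability of planted
discrete structure at realistic depth — not robustness to every artifact
of real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale experiments:
the default configuration is 6 plates (2,280 cell wells, ~2.2 M reads),
the retention brute-force check uses 5,000 cells, and clustering
recovery uses 2,000 cells over 5 seeds — sizes chosen so the full suite
completes in minutes on one CPU while keeping every stated parameter of
the method (K = 150, 1,000 resamples at 75%, K = 30/α = 2/
min_mc_size = 30) at its atlas value. Degenerate inputs are handled
explicitly: empty matrices and all-outlier partitions raise; unknown
chromosomes, missing animal ids and metacells without bacterial signal
degrade gracefully with logged reasons. Co-occurrence matrices are held
dense (float64 n×n), which is comfortable to ~10⁴ cells; beyond that a
sparse accumulation would be needed.

## Known limitations

* The clustering is a faithful re-parameterization of the bootstrapped
  metacell approach, not a numerical replica of the published R
  package's internals; on continuous manifolds the natural-boundary
  stopping rule will under-partition relative to fixed-size metacell
  covers.
* The IVT filter's binomial null is a stand-in for the original
  (unpublished) statistic and is deliberately permissive at q < 0.2.
* Barcode sequencing errors across wells, ambient-RNA decontamination
  and doublet detection are out of scope.
* Accession-scale inputs (tens of thousands of cells) would need the
  sparse co-occurrence accumulation noted above.
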