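"""Ground-truthed synthetic MARS-seq experiment generator.

Emulates the statistical structure the pipeline assumes so that every
stage is testable without external downloads:

* 384-well capture plates, 4 empty control wells per plate (ambient-only
  barcodes, the cell filter's true negatives);
* per-cell UMI depth log-normal with a median of a few hundred molecules;
* cell-type-specific expression programs (disjoint marker sets with a
  configurable fold over baseline);
* 3'-biased read positions, with a per-gene unannotated 3' UTR overhang
  so interval extension has real signal to rescue;
* hidden (unannotated) genes whose reads fall in intergenic 2-kb windows,
  exercising bin rescue;
* two intracellular bacteria carried as separate non-host "chromosomes",
  planted in subsets of cell types with per-animal infection scaling and
  a small ambient background.

Reads are strand-specific (the protocol is 3'-stranded) and carry plate,
well, cell barcode, UMI, position, strand and a unique-mapping flag.
Everything is deterministic for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    KIND_BACTERIAL,
    KIND_GENE,
    GeneInterval,
)
from .config import SimulationConfig

SYMBIONT_A = "symbiontA_genome"  # Chlamydia-related
SYMBIONT_B = "symbiontB_genome"  # Gammaproteobacteria-related
SYMBIONT_GENOME_SIZE = 200_000

_LETTERS = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticAnnotation:
    """Annotated features plus the generator's private truth about them."""

    features: list[GeneInterval]
    chrom_sizes: dict[str, int]
    # per expressed transcript (annotated genes then hidden genes):
    # chrom, tx_start, tx_end (includes UTR overhang), strand, hidden flag
    gene_table: pd.DataFrame = field(repr=False, default=None)


@dataclass
class SyntheticTruth:
    """Planted ground truth: one record per non-empty well."""

    cells: pd.DataFrame          # barcode, plate, well, animal, cell_type, depth, n_sym_a, n_sym_b
    genes: pd.DataFrame          # id, marker_of, hidden
    molecules: pd.DataFrame      # barcode, feature_id, n_molecules (host only)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def plate_layout(config: SimulationConfig) -> pd.DataFrame:
    """Well layout: one row per well with plate, well, barcode, is_empty,
    animal. Empty control wells are chosen per plate from the run seed."""
    rng = _rng(config.seed, 0)
    rows = []
    for plate in range(config.n_plates):
        empties = set(
            rng.choice(config.wells_per_plate,
                       size=config.empty_wells_per_plate, replace=False)
        )
        animal = plate * config.n_animals // config.n_plates
        for well in range(config.wells_per_plate):
            rows.append(
                (plate, well, f"P{plate:02d}_W{well:03d}", well in empties, animal)
            )
    return pd.DataFrame(
        rows, columns=["plate", "well", "barcode", "is_empty", "animal"]
    )


def sample_depths(config: SimulationConfig, n: int,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-cell molecule depths: log-normal with the configured median."""
    if rng is None:
        rng = _rng(config.seed, 9)
    d = rng.lognormal(mean=np.log(config.depth_median),
                      sigma=config.depth_sigma, size=n)
    return np.maximum(1, np.rint(d)).astype(np.int64)


def simulate_annotation(config: SimulationConfig) -> SyntheticAnnotation:
    """Place non-overlapping stranded genes on host chromosomes, reserve
    intergenic 2-kb windows for hidden genes, and append the two bacterial
    genomes as whole-chromosome features."""
    config.validate()
    rng = _rng(config.seed, 1)
    n_chrom = config.n_chromosomes
    genes_per_chrom = [
        config.n_genes // n_chrom + (1 if c < config.n_genes % n_chrom else 0)
        for c in range(n_chrom)
    ]
    hidden_per_chrom = [
        config.n_hidden_genes // n_chrom
        + (1 if c < config.n_hidden_genes % n_chrom else 0)
        for c in range(n_chrom)
    ]
    features: list[GeneInterval] = []
    chrom_sizes: dict[str, int] = {}
    rows = []  # id, chrom, start, end, strand, hidden
    gi = 0
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        pos = 0
        last_end = 0
        for _ in range(genes_per_chrom[c]):
            gap = int(rng.integers(200, 3001))
            length = int(rng.integers(500, 3001))
            start = pos + gap
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            fid = f"g{gi:04d}"
            features.append(GeneInterval(chrom, start, end, strand, fid, KIND_GENE))
            rows.append((fid, chrom, start, end, strand, False))
            gi += 1
            pos = end
            last_end = end
        # hidden-gene windows: past the last extension reach, 2-kb aligned
        h = ((last_end + 3000 + 1999) // 2000) * 2000
        for k in range(hidden_per_chrom[c]):
            start, end = h, h + 2000
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"hidden_{chrom}_{start}", chrom, start, end, strand, True))
            h = end + 2000
        chrom_sizes[chrom] = h + 1000 if hidden_per_chrom[c] else last_end + 2000

    for name in (SYMBIONT_A, SYMBIONT_B):
        chrom_sizes[name] = SYMBIONT_GENOME_SIZE
        features.append(
            GeneInterval(name, 0, SYMBIONT_GENOME_SIZE, "+", name, KIND_BACTERIAL)
        )

    gene_table = pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "strand", "hidden"]
    )
    # unannotated 3' UTR overhang, bounded by the downstream same-strand
    # neighbor so interval extension can recover every overhung read
    overhang = np.zeros(len(gene_table), dtype=np.int64)
    ann = gene_table[~gene_table["hidden"]]
    for (chrom, strand), grp in ann.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("start")
        idx = grp.index.to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        size = chrom_sizes[chrom]
        if strand == "+":
            nxt = np.append(starts[1:], size)
            room = np.minimum(nxt - ends, 1000)
        else:
            prev = np.concatenate(([0], ends[:-1]))
            room = np.minimum(starts - prev, 1000)
        room = np.minimum(room, config.max_utr_overhang_bp)
        overhang[idx] = rng.integers(0, np.maximum(room, 0) + 1)
    gene_table["overhang"] = overhang
    tx_start = gene_table["start"].to_numpy().copy()
    tx_end = gene_table["end"].to_numpy().copy()
    plus = gene_table["strand"].to_numpy() == "+"
    tx_end[plus] += overhang[plus]
    tx_start[~plus] -= overhang[~plus]
    gene_table["tx_start"] = tx_start
    gene_table["tx_end"] = tx_end
    return SyntheticAnnotation(features, chrom_sizes, gene_table)


def _type_weights(config: SimulationConfig, gene_table: pd.DataFrame,
                  marker_of: np.ndarray) -> np.ndarray:
    """(n_types, n_transcripts) expression weights."""
    n_tx = len(gene_table)
    hidden = gene_table["hidden"].to_numpy()
    w = np.ones((config.n_cell_types, n_tx))
    w[:, hidden] = config.hidden_gene_weight
    for t in range(config.n_cell_types):
        w[t, marker_of == t] = config.marker_fold
    return w / w.sum(axis=1, keepdims=True)


def _umi_strings(codes: np.ndarray, length: int) -> np.ndarray:
    chars = np.empty((len(codes), length), dtype="S1")
    for i in range(length):
        shift = 2 * (length - 1 - i)
        chars[:, i] = _LETTERS[(codes >> shift) & 3]
    return chars.view(f"S{length}").ravel().astype(str)


def umi_codes_from_strings(umis: np.ndarray | pd.Series, length: int) -> np.ndarray:
    """Inverse of the 2-bit UMI encoding; raises on unequal lengths."""
    arr = np.asarray(umis, dtype=f"S{length + 1}")
    lens = np.char.str_len(arr)
    if len(arr) and not (lens == length).all():
        raise ValueError("UMIs of unequal length")
    bytes_ = arr.astype(f"S{length}").view("S1").reshape(len(arr), length)
    lut = np.zeros(256, dtype=np.int64)
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    vals = lut[bytes_.view(np.uint8)]
    powers = 4 ** np.arange(length - 1, -1, -1, dtype=np.int64)
    return vals @ powers


def _draw_group_unique_umis(group_key: np.ndarray, n_codes: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Uniform UMI codes, distinct within each group (molecules of one
    cell x feature never collide, so planted molecule counts are exact
    in the zero-error regime)."""
    n = len(group_key)
    codes = rng.integers(0, n_codes, size=n, dtype=np.int64)
    for _ in range(64):
        order = np.lexsort((codes, group_key))
        gk, ck = group_key[order], codes[order]
        dup_sorted = np.zeros(n, dtype=bool)
        dup_sorted[1:] = (gk[1:] == gk[:-1]) & (ck[1:] == ck[:-1])
        dup = np.zeros(n, dtype=bool)
        dup[order] = dup_sorted
        if not dup.any():
            return codes
        codes[dup] = rng.integers(0, n_codes, size=int(dup.sum()), dtype=np.int64)
    raise RuntimeError("UMI space too small for molecule multiplicity")


def simulate_reads(config: SimulationConfig,
                   annotation: SyntheticAnnotation
                   ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the read table and its planted truth.

    Returns ``(reads, truth)`` where ``reads`` has columns plate, well,
    barcode, chrom, pos, strand, umi, unique_flag and ``truth`` records
    every non-empty well's type, depth and infection state plus per-cell
    per-gene planted molecule counts.
    """
    config.validate()
    gene_table = annotation.gene_table
    if gene_table is None:
        raise ValueError("annotation must come from simulate_annotation")
    n_tx = len(gene_table)
    marker_of = np.full(n_tx, -1, dtype=np.int64)
    annotated_idx = np.flatnonzero(~gene_table["hidden"].to_numpy())
    need = config.n_cell_types * config.genes_per_type_marker
    if need > len(annotated_idx):
        raise ValueError("marker programs exceed the number of annotated genes")
    for t in range(config.n_cell_types):
        sel = annotated_idx[t * config.genes_per_type_marker:
                            (t + 1) * config.genes_per_type_marker]
        marker_of[sel] = t
    weights = _type_weights(config, gene_table, marker_of)

    rng_cells = _rng(config.seed, 2)
    rng_reads = _rng(config.seed, 3)

    layout = plate_layout(config)
    cells = layout[~layout["is_empty"]].reset_index(drop=True).copy()
    n_cells = len(cells)
    cells["cell_type"] = rng_cells.choice(
        config.n_cell_types, size=n_cells, p=np.asarray(config.type_proportions)
    )
    cells["depth"] = sample_depths(config, n_cells, rng_cells)

    scale = np.asarray(config.animal_infection_scale, dtype=float)
    if len(scale) < config.n_animals:
        scale = np.resize(scale, config.n_animals)
    p_a = np.zeros(config.n_cell_types)
    p_b = np.zeros(config.n_cell_types)
    for t, p in config.infection_prob_a.items():
        p_a[t] = p
    for t, p in config.infection_prob_b.items():
        p_b[t] = p
    cell_pa = np.clip(p_a[cells["cell_type"]] * scale[cells["animal"]], 0, 1)
    cell_pb = np.clip(p_b[cells["cell_type"]] * scale[cells["animal"]], 0, 1)
    inf_a = rng_cells.random(n_cells) < cell_pa
    inf_b = rng_cells.random(n_cells) < cell_pb

    def _loads(mask: np.ndarray) -> np.ndarray:
        out = np.zeros(n_cells, dtype=np.int64)
        k = int(mask.sum())
        if k:
            draw = rng_cells.lognormal(np.log(config.symbiont_load_median),
                                       config.symbiont_load_sigma, size=k)
            out[mask] = np.maximum(1, np.rint(draw)).astype(np.int64)
        return out

    load_a = _loads(inf_a)
    load_b = _loads(inf_b)
    # ambient stray bacterial molecules in uninfected cells and empty wells
    amb_a = rng_cells.poisson(config.ambient_rate, size=n_cells) * (~inf_a)
    amb_b = rng_cells.poisson(config.ambient_rate, size=n_cells) * (~inf_b)
    n_sym_a = load_a + amb_a
    n_sym_b = load_b + amb_b

    cells["n_sym_a"] = n_sym_a
    cells["n_sym_b"] = n_sym_b
    cells["infected_a"] = inf_a
    cells["infected_b"] = inf_b

    # -- host molecules ----------------------------------------------------
    depth = cells["depth"].to_numpy()
    mol_cell = np.repeat(np.arange(n_cells), depth)
    mol_gene = np.empty(len(mol_cell), dtype=np.int64)
    ctype_per_mol = np.repeat(cells["cell_type"].to_numpy(), depth)
    for t in range(config.n_cell_types):
        m = ctype_per_mol == t
        if m.any():
            mol_gene[m] = rng_cells.choice(n_tx, size=int(m.sum()), p=weights[t])

    # -- ambient host molecules in empty control wells ---------------------
    empties = layout[layout["is_empty"]].reset_index(drop=True)
    amb_counts = rng_cells.poisson(config.ambient_host_rate, size=len(empties))
    amb_cell = np.repeat(np.arange(len(empties)), amb_counts)
    mean_w = weights.mean(axis=0)
    mean_w = mean_w / mean_w.sum()
    amb_gene = (rng_cells.choice(n_tx, size=len(amb_cell), p=mean_w)
                if len(amb_cell) else np.empty(0, dtype=np.int64))
    amb_sym_a = rng_cells.poisson(config.ambient_rate, size=len(empties))
    amb_sym_b = rng_cells.poisson(config.ambient_rate, size=len(empties))

    # -- assemble the molecule table ---------------------------------------
    # well index space: cells then empty wells
    all_barcodes = np.concatenate(
        [cells["barcode"].to_numpy(), empties["barcode"].to_numpy()]
    )
    all_plates = np.concatenate(
        [cells["plate"].to_numpy(), empties["plate"].to_numpy()]
    )
    all_wells = np.concatenate(
        [cells["well"].to_numpy(), empties["well"].to_numpy()]
    )
    n_all = len(all_barcodes)

    # feature index space: transcripts, then symbiont A (=n_tx), B (=n_tx+1)
    SYM_A_IDX, SYM_B_IDX = n_tx, n_tx + 1
    mol_well = [mol_cell, amb_cell + n_cells]
    mol_feat = [mol_gene, amb_gene]
    for sym_idx, counts_c, counts_e in (
        (SYM_A_IDX, n_sym_a, amb_sym_a),
        (SYM_B_IDX, n_sym_b, amb_sym_b),
    ):
        mol_well.append(np.repeat(np.arange(n_cells), counts_c))
        mol_feat.append(np.full(int(counts_c.sum()), sym_idx, dtype=np.int64))
        mol_well.append(np.repeat(np.arange(len(empties)), counts_e) + n_cells)
        mol_feat.append(np.full(int(counts_e.sum()), sym_idx, dtype=np.int64))
    mol_well_arr = np.concatenate(mol_well)
    mol_feat_arr = np.concatenate(mol_feat)
    n_mol = len(mol_well_arr)

    group_key = mol_well_arr * np.int64(n_tx + 2) + mol_feat_arr
    umi_codes = _draw_group_unique_umis(
        group_key, 4 ** config.umi_length, rng_reads
    )

    # -- expand molecules into reads ---------------------------------------
    n_reads_per_mol = rng_reads.geometric(1.0 / config.reads_per_umi, size=n_mol)
    read_mol = np.repeat(np.arange(n_mol), n_reads_per_mol)
    n_reads = len(read_mol)
    r_well = mol_well_arr[read_mol]
    r_feat = mol_feat_arr[read_mol]
    r_code = umi_codes[read_mol].copy()

    # per-read UMI errors: single-base perturbation
    if config.umi_error_rate > 0:
        err = rng_reads.random(n_reads) < config.umi_error_rate
        k = int(err.sum())
        if k:
            pos_b = rng_reads.integers(0, config.umi_length, size=k)
            delta = rng_reads.integers(1, 4, size=k)
            shift = 2 * (config.umi_length - 1 - pos_b)
            cur = (r_code[err] >> shift) & 3
            new = (cur + delta) % 4
            r_code[err] ^= (cur ^ new) << shift

    # positions: genes biased toward the (possibly overhung) 3' end
    tx_start = gene_table["tx_start"].to_numpy()
    tx_end = gene_table["tx_end"].to_numpy()
    tx_strand = (gene_table["strand"].to_numpy() == "+")
    tx_chrom = gene_table["chrom"].to_numpy()

    r_pos = np.empty(n_reads, dtype=np.int64)
    r_strand = np.empty(n_reads, dtype="U1")
    r_chrom = np.empty(n_reads, dtype=object)

    host = r_feat < n_tx
    hf = r_feat[host]
    s0, e0 = tx_start[hf], tx_end[hf]
    plus = tx_strand[hf]
    u = rng_reads.random(int(host.sum()))
    biased = rng_reads.random(int(host.sum())) < config.bias_3prime
    lo = s0.copy()
    hi = e0.copy()
    w = config.bias_window_bp
    # biased reads: uniform in the 3'-most window of the transcript
    lo_b = np.where(plus, np.maximum(s0, e0 - w), s0)
    hi_b = np.where(plus, e0, np.minimum(e0, s0 + w))
    lo = np.where(biased, lo_b, lo)
    hi = np.where(biased, hi_b, hi)
    r_pos[host] = lo + np.floor(u * (hi - lo)).astype(np.int64)
    r_strand[host] = np.where(plus, "+", "-")
    r_chrom[host] = tx_chrom[hf]

    for sym_idx, name in ((SYM_A_IDX, SYMBIONT_A), (SYM_B_IDX, SYMBIONT_B)):
        m = r_feat == sym_idx
        k = int(m.sum())
        r_pos[m] = rng_reads.integers(0, SYMBIONT_GENOME_SIZE, size=k)
        r_strand[m] = np.where(rng_reads.random(k) < 0.5, "+", "-")
        r_chrom[m] = name

    unique_flag = rng_reads.random(n_reads) >= config.nonunique_rate

    reads = pd.DataFrame(
        {
            "plate": all_plates[r_well],
            "well": all_wells[r_well],
            "barcode": all_barcodes[r_well],
            "chrom": r_chrom.astype(str),
            "pos": r_pos,
            "strand": r_strand,
            "umi": _umi_strings(r_code, config.umi_length),
            "unique_flag": unique_flag,
        }
    )

    # -- truth -------------------------------------------------------------
    host_mask = mol_feat_arr < n_tx
    cell_mask = mol_well_arr < n_cells
    hm = host_mask & cell_mask
    mol_df = pd.DataFrame(
        {
            "barcode": all_barcodes[mol_well_arr[hm]],
            "feature_id": gene_table["id"].to_numpy()[mol_feat_arr[hm]],
        }
    )
    molecules = (
        mol_df.groupby(["barcode", "feature_id"], sort=True)
        .size().rename("n_molecules").reset_index()
    )
    genes = pd.DataFrame(
        {
            "id": gene_table["id"],
            "marker_of": np.where(marker_of >= 0, marker_of, -1),
            "hidden": gene_table["hidden"],
        }
    )
    truth_cells = cells[
        ["barcode", "plate", "well", "animal", "cell_type", "depth",
         "n_sym_a", "n_sym_b", "infected_a", "infected_b"]
    ].copy()
    return reads, SyntheticTruth(truth_cells, genes, molecules)
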