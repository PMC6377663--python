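"""Synthetic barcoding experiments with known ground truth.

Generates an experiment end to end: a barcode library, engrafted clones
with a heavy-tailed size distribution, patchy tumor-piece profiles,
blood/lung tissue profiles with shedder/seeder structure, replicate-level
read counts with depth variation and single-replicate contaminant
barcodes, and (optionally) raw FASTQ reads wrapping each barcode in the
amplicon design.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

import numpy as np
import pandas as pd

from .barcode_io import (
    META_COLUMNS,
    AmpliconDesign,
    BarcodeCountMatrix,
    BarcodeLibrary,
    SampleSheet,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "random_library",
    "generate_ground_truth",
    "synthesize_counts",
    "render_reads",
    "generate_experiment",
]


@dataclass(frozen=True)
class SyntheticConfig:
    library_size: int = 2500
    n_injected: int = 2500
    engraft_prob: float = 0.10
    clone_size_distribution: str = "log_normal"  # or "pareto"
    log_normal_mu: float = 0.0
    log_normal_sigma: float = 2.5
    pareto_alpha: float = 1.0
    n_tumor_pieces: int = 8
    sigma_shed: float = 0.5
    shedder_fraction: float = 1.0
    seeder_fraction: float = 0.2
    n_replicates_per_sample: int = 2
    mean_reads_per_replicate: int = 50_000
    frac_replicates_below_depth: float = 0.0
    depth_threshold: int = 8000
    spurious_barcode_rate: float = 0.0
    treatment_survival_prob: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "engraft_prob",
            "shedder_fraction",
            "seeder_fraction",
            "frac_replicates_below_depth",
            "treatment_survival_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.library_size < self.n_injected:
            raise ValueError("library_size must be >= n_injected")
        if self.sigma_shed < 0 or self.spurious_barcode_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_tumor_pieces < 2:
            raise ValueError("n_tumor_pieces must be >= 2")


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic mouse."""

    engrafted: list[str]
    tissue_truth: dict[str, pd.Series]  # tissue -> frequency vector (sums to 1)
    shedders: set[str]
    seeders: set[str]
    config: SyntheticConfig
    spurious_by_replicate: dict[str, list[str]] = field(default_factory=dict)

    def tumor_frequencies(self) -> pd.Series:
        return self.tissue_truth["tumor"]


def random_library(
    size: int, barcode_length: int = 98, seed: int | np.random.Generator = 0
) -> BarcodeLibrary:
    """Random semi-random barcode library with unique sequences."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bases = np.array(list("ACGT"))
    entries: dict[str, str] = {}
    seen: set[str] = set()
    i = 0
    while len(entries) < size:
        seq = "".join(bases[rng.integers(0, 4, barcode_length)])
        if seq not in seen:
            seen.add(seq)
            entries[f"BC{i:04d}"] = seq
            i += 1
    return BarcodeLibrary(entries=entries)


def _clone_sizes(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.clone_size_distribution == "log_normal":
        sizes = rng.lognormal(cfg.log_normal_mu, cfg.log_normal_sigma, n)
    elif cfg.clone_size_distribution == "pareto":
        sizes = 1.0 + rng.pareto(cfg.pareto_alpha, n)
    else:
        raise ValueError(
            f"unknown clone_size_distribution {cfg.clone_size_distribution!r}"
        )
    return sizes / sizes.sum()


def _patchy_pieces(
    freqs: pd.Series, n_pieces: int, rng: np.random.Generator
) -> dict[str, pd.Series]:
    """Allocate each clone to a contiguous run of pieces on a chain.

    Larger clones span more pieces (dispersion grows with clone size);
    within its run a clone's mass is split by a Dirichlet draw, so
    adjacent pieces share clones.
    """
    ranks = freqs.rank(pct=True).to_numpy()
    piece_mass = np.zeros((n_pieces, len(freqs)))
    for j, (bc, f) in enumerate(freqs.items()):
        span = 1 + int(np.floor(ranks[j] * n_pieces * rng.uniform(0.5, 1.0)))
        span = min(span, n_pieces)
        start = rng.integers(0, n_pieces - span + 1)
        weights = rng.dirichlet(np.ones(span))
        piece_mass[start : start + span, j] = f * weights
    out = {}
    for k in range(n_pieces):
        col = pd.Series(piece_mass[k], index=freqs.index)
        col = col[col > 0]
        total = col.sum()
        out[f"tumor_piece_{k + 1}"] = col / total if total > 0 else col
    return out


def _lognormal_perturb(
    freqs: pd.Series, sigma: float, rng: np.random.Generator
) -> pd.Series:
    noisy = freqs * rng.lognormal(0.0, sigma, len(freqs))
    return noisy / noisy.sum()


def generate_ground_truth(
    cfg: SyntheticConfig, seed: int | np.random.Generator = 0
) -> SyntheticTruth:
    """Draw the engrafted clone set and per-tissue true frequencies.

    Engraftment is Binomial(n_injected, engraft_prob); clone sizes follow
    the configured heavy-tailed law; tumor pieces get a patchy allocation;
    blood is the tumor profile under multiplicative shedding noise; lung
    at T3 is supported only on the seeder subset.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    injected = [f"BC{i:04d}" for i in range(cfg.n_injected)]
    engraft_mask = rng.random(cfg.n_injected) < cfg.engraft_prob
    engrafted = [bc for bc, ok in zip(injected, engraft_mask) if ok]

    tissue_truth: dict[str, pd.Series] = {}
    shedders: set[str] = set()
    seeders: set[str] = set()
    if engrafted:
        tumor = pd.Series(_clone_sizes(cfg, len(engrafted), rng), index=engrafted)
        tissue_truth["tumor"] = tumor
        tissue_truth.update(_patchy_pieces(tumor, cfg.n_tumor_pieces, rng))

        shed_mask = rng.random(len(engrafted)) < cfg.shedder_fraction
        shedders = {bc for bc, ok in zip(engrafted, shed_mask) if ok}
        if shedders:
            shed = tumor.loc[sorted(shedders)]
            blood = _lognormal_perturb(shed, cfg.sigma_shed, rng)
            tissue_truth["blood"] = blood
            lung = _lognormal_perturb(shed, cfg.sigma_shed, rng)
            tissue_truth["lung"] = lung

            seed_mask = rng.random(len(shedders)) < cfg.seeder_fraction
            seeders = {bc for bc, ok in zip(sorted(shedders), seed_mask) if ok}
            if seeders:
                # post-resection outgrowth is uncorrelated with parental size
                sizes = rng.lognormal(0.0, cfg.log_normal_sigma, len(seeders))
                lung_t3 = pd.Series(sizes / sizes.sum(), index=sorted(seeders))
                tissue_truth["lung_T3"] = lung_t3
            else:
                tissue_truth["lung_T3"] = pd.Series(dtype=float)
        else:
            tissue_truth["blood"] = pd.Series(dtype=float)
            tissue_truth["lung"] = pd.Series(dtype=float)
            tissue_truth["lung_T3"] = pd.Series(dtype=float)
    else:
        tissue_truth["tumor"] = pd.Series(dtype=float)

    return SyntheticTruth(
        engrafted=engrafted,
        tissue_truth=tissue_truth,
        shedders=shedders,
        seeders=seeders,
        config=cfg,
    )


_TISSUE_TIMEPOINT = {"lung_T3": "T3"}


def _draw_depth(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    if rng.random() < cfg.frac_replicates_below_depth:
        return int(rng.integers(500, cfg.depth_threshold))
    lo = cfg.depth_threshold
    hi = max(2 * cfg.mean_reads_per_replicate - lo, lo + 1)
    return int(rng.integers(lo, hi))


def synthesize_counts(
    truth: SyntheticTruth,
    seed: int | np.random.Generator = 0,
    mouse_id: str = "M1",
    run_id: str = "R1",
    tissues: list[str] | None = None,
) -> BarcodeCountMatrix:
    """Render ground truth into a replicate-level read-count matrix.

    Per replicate, reads are multinomial over the tissue truth at a depth
    drawn so the configured fraction of replicates falls below the
    threshold.  Each spurious contaminant barcode (drawn from the
    unengrafted remainder of the library) lands in exactly one replicate
    at low count.  Sorted cell counts are recorded for blood/lung samples.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tissues = tissues if tissues is not None else list(truth.tissue_truth)
    all_barcodes = [f"BC{i:04d}" for i in range(cfg.library_size)]
    unengrafted = [bc for bc in all_barcodes if bc not in set(truth.engrafted)]

    meta_rows = []
    count_rows = {}
    for tissue in tissues:
        freqs = truth.tissue_truth[tissue]
        sample_id = f"{mouse_id}_{tissue}"
        timepoint = _TISSUE_TIMEPOINT.get(tissue, "T2")
        sorted_cells = (
            int(freqs.size * 50) if tissue in ("blood", "lung", "lung_T3") else pd.NA
        )
        n_spurious = rng.poisson(cfg.spurious_barcode_rate)
        spurious = (
            list(rng.choice(unengrafted, size=min(n_spurious, len(unengrafted)), replace=False))
            if n_spurious and unengrafted
            else []
        )
        for r in range(1, cfg.n_replicates_per_sample + 1):
            rep_id = f"rep{r}"
            key = f"{sample_id}.{rep_id}"
            depth = _draw_depth(cfg, rng)
            row = dict.fromkeys(all_barcodes, 0)
            if len(freqs) > 0:
                draw = rng.multinomial(depth, freqs.to_numpy() / freqs.sum())
                for bc, c in zip(freqs.index, draw):
                    row[bc] = int(c)
            count_rows[key] = row
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "index_sequence": _index_for(len(meta_rows)),
                    "mouse_id": mouse_id,
                    "tissue": tissue,
                    "timepoint": timepoint,
                    "replicate_id": rep_id,
                    "run_id": run_id,
                    "sorted_cell_count": sorted_cells,
                }
            )
        # contaminants: each into exactly one replicate of this sample
        for bc in spurious:
            r = int(rng.integers(1, cfg.n_replicates_per_sample + 1))
            key = f"{sample_id}.rep{r}"
            count_rows[key][bc] += int(1 + rng.poisson(3))
            truth.spurious_by_replicate.setdefault(key, []).append(bc)

    keys = list(count_rows)
    counts = pd.DataFrame.from_dict(count_rows, orient="index", dtype=int)
    counts = counts.reindex(columns=all_barcodes, fill_value=0)
    counts.index = pd.Index(keys, name="row_key")
    meta = pd.DataFrame(meta_rows, index=pd.Index(keys, name="row_key"))
    meta["sorted_cell_count"] = meta["sorted_cell_count"].astype("Int64")
    return BarcodeCountMatrix(counts=counts, meta=meta)


def _index_for(i: int) -> str:
    """Deterministic distinct 8-mer index for replicate row i."""
    bases = "ACGT"
    return "".join(bases[(i >> (2 * k)) & 3] for k in range(8))


def generate_experiment(
    cfg: SyntheticConfig, seed: int = 0, mouse_id: str = "M1"
) -> tuple[SyntheticTruth, BarcodeCountMatrix]:
    """Convenience: ground truth plus counts from one seed."""
    rng = np.random.default_rng(seed)
    truth = generate_ground_truth(cfg, rng)
    matrix = synthesize_counts(truth, rng, mouse_id=mouse_id)
    return truth, matrix


def render_reads(
    matrix: BarcodeCountMatrix,
    library: BarcodeLibrary,
    design: AmpliconDesign,
    handle: IO[str],
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> int:
    """Write FASTQ reads reconstructing each counted barcode observation.

    Each read is index + 5' flank + barcode + 3' flank, padded with 'A'
    to the product length, with optional uniform substitution errors.
    Returns the number of reads written.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_written = 0
    bases = "ACGT"
    for key in matrix.counts.index:
        index_seq = matrix.meta.at[key, "index_sequence"]
        row = matrix.counts.loc[key]
        for bc_id in row.index[row.to_numpy() > 0]:
            seq = library.entries.get(bc_id)
            if seq is None:
                continue
            read = index_seq + design.flank_5p + seq + design.flank_3p
            read = read[: design.product_length].ljust(design.product_length, "A")
            for _ in range(int(row[bc_id])):
                out = read
                if error_rate > 0:
                    chars = list(out)
                    hits = np.flatnonzero(rng.random(len(chars)) < error_rate)
                    for h in hits:
                        chars[h] = bases[rng.integers(0, 4)]
                    out = "".join(chars)
                n_written += 1
                handle.write(
                    f"@synth_{n_written} {key} {bc_id}\n{out}\n+\n{'I' * len(out)}\n"
                )
    return n_written


def sample_sheet_from_matrix(matrix: BarcodeCountMatrix) -> SampleSheet:
    """Recover a SampleSheet view of a synthetic matrix's metadata."""
    return SampleSheet(rows=matrix.meta[META_COLUMNS].reset_index(drop=True))
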