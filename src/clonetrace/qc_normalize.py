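"""Depth and replicate-support filtering, replicate pooling, normalization.

The filter chain is fixed: drop replicate rows below the read-depth
threshold (and samples left with too few surviving replicates), zero out
barcodes seen in too few technical replicates of a sample, then pool
replicates and normalize each sample's counts to a frequency profile
summing to one.  Replicates from different sequencing runs are each
normalized before pooling to mitigate library-size differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode_io import BarcodeCountMatrix

__all__ = [
    "QCConfig",
    "ClonalProfile",
    "QCReport",
    "filter_replicates_by_depth",
    "filter_barcodes_by_replicate_support",
    "pool_and_normalize",
    "run_qc",
    "profiles_to_frame",
    "frame_to_profiles",
]

FREQ_TOL = 1e-9


@dataclass(frozen=True)
class QCConfig:
    min_reads_per_replicate: int = 8000
    min_supporting_replicates: int = 2
    min_replicates_per_sample: int = 2

    def __post_init__(self) -> None:
        for name in (
            "min_reads_per_replicate",
            "min_supporting_replicates",
            "min_replicates_per_sample",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class QCReport:
    """Per-row/sample removals with reasons, for audit."""

    dropped_replicates: list[dict] = field(default_factory=list)
    dropped_samples: list[dict] = field(default_factory=list)
    zeroed_barcodes: list[dict] = field(default_factory=list)
    empty_profiles: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_replicates": self.dropped_replicates,
            "dropped_samples": self.dropped_samples,
            "zeroed_barcodes": self.zeroed_barcodes,
            "empty_profiles": self.empty_profiles,
        }


@dataclass
class ClonalProfile:
    """Normalized per-sample barcode frequencies (zeros dropped).

    ``frequencies`` is indexed by barcode id, strictly positive, and sums
    to 1 (within 1e-9) whenever any barcode was detected.
    """

    sample_id: str
    frequencies: pd.Series
    n_barcodes_detected: int = None  # type: ignore[assignment]
    provenance: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        freqs = self.frequencies[self.frequencies > 0].astype(float)
        object.__setattr__(self, "frequencies", freqs)
        if self.n_barcodes_detected is None:
            self.n_barcodes_detected = len(freqs)
        if len(freqs) and abs(freqs.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"profile {self.sample_id!r} frequencies sum to {freqs.sum():.6g}, not 1"
            )

    @property
    def is_empty(self) -> bool:
        return self.n_barcodes_detected == 0

    @property
    def barcodes(self) -> set[str]:
        return set(self.frequencies.index)

    def __repr__(self) -> str:
        return (
            f"ClonalProfile({self.sample_id!r}, n_barcodes={self.n_barcodes_detected})"
        )


def filter_replicates_by_depth(
    matrix: BarcodeCountMatrix, cfg: QCConfig = QCConfig()
) -> tuple[BarcodeCountMatrix, QCReport]:
    """Drop low-depth replicate rows, then under-replicated samples.

    A replicate row is removed when its total assigned reads fall below
    ``min_reads_per_replicate``; a sample is removed entirely when fewer
    than ``min_replicates_per_sample`` of its rows survive.
    """
    report = QCReport()
    totals = matrix.row_totals()
    deep = totals >= cfg.min_reads_per_replicate
    for key in matrix.counts.index[~deep]:
        report.dropped_replicates.append(
            {
                "row_key": key,
                "sample_id": matrix.meta.at[key, "sample_id"],
                "reads": int(totals[key]),
                "reason": f"total reads {int(totals[key])} < {cfg.min_reads_per_replicate}",
            }
        )
    kept = matrix.subset_rows(matrix.counts.index[deep])
    surviving = kept.sample_groups()
    keep_keys: list[str] = []
    for sid in matrix.sample_groups():
        keys = surviving.get(sid, [])
        if len(keys) < cfg.min_replicates_per_sample:
            report.dropped_samples.append(
                {
                    "sample_id": sid,
                    "surviving_replicates": len(keys),
                    "reason": (
                        f"only {len(keys)} replicate(s) with >= "
                        f"{cfg.min_reads_per_replicate} reads "
                        f"(need {cfg.min_replicates_per_sample})"
                    ),
                }
            )
        else:
            keep_keys.extend(keys)
    return kept.subset_rows(keep_keys), report


def filter_barcodes_by_replicate_support(
    matrix: BarcodeCountMatrix, cfg: QCConfig = QCConfig()
) -> BarcodeCountMatrix:
    """Zero out, per sample, barcodes detected in too few replicates.

    "Detected" means count >= 1.  Requires every sample to retain at
    least ``min_supporting_replicates`` rows; run
    :func:`filter_replicates_by_depth` first.
    """
    counts = matrix.counts.copy()
    for sid, keys in matrix.sample_groups().items():
        if len(keys) < cfg.min_supporting_replicates:
            raise ValueError(
                f"sample {sid!r} has {len(keys)} replicate(s), fewer than "
                f"min_supporting_replicates={cfg.min_supporting_replicates}; "
                "apply filter_replicates_by_depth first"
            )
        block = counts.loc[keys]
        support = (block > 0).sum(axis=0)
        weak = support.index[(support > 0) & (support < cfg.min_supporting_replicates)]
        if len(weak):
            counts.loc[keys, weak] = 0
    return BarcodeCountMatrix(
        counts=counts, meta=matrix.meta.copy(), unassigned=matrix.unassigned.copy()
    )


def _pool_sample(block: pd.DataFrame, runs: pd.Series) -> pd.Series:
    """Pool replicate count rows into one frequency vector summing to 1."""
    if runs.nunique() == 1:
        pooled = block.sum(axis=0).astype(float)
        total = pooled.sum()
        return pooled / total if total > 0 else pooled
    # cross-run: normalize each replicate, sum, renormalize
    row_totals = block.sum(axis=1).astype(float)
    nonzero = row_totals > 0
    if not nonzero.any():
        return block.sum(axis=0).astype(float)
    normed = block.loc[nonzero].div(row_totals[nonzero], axis=0)
    pooled = normed.sum(axis=0)
    return pooled / pooled.sum()


def pool_and_normalize(matrix: BarcodeCountMatrix) -> list[ClonalProfile]:
    """Pool technical replicates per sample and normalize to frequencies.

    Same-run replicates are pooled by summing raw counts; replicates
    spanning sequencing runs are first normalized to one each, then
    summed and renormalized.  Samples with zero total reads yield an
    empty profile (flagged, with a warning).
    """
    profiles: list[ClonalProfile] = []
    for sid, keys in matrix.sample_groups().items():
        block = matrix.counts.loc[keys]
        runs = matrix.meta.loc[keys, "run_id"]
        freqs = _pool_sample(block, runs)
        meta_row = matrix.meta.loc[keys[0]]
        meta = {
            "mouse_id": meta_row["mouse_id"],
            "tissue": meta_row["tissue"],
            "timepoint": meta_row["timepoint"],
            "sorted_cell_count": meta_row["sorted_cell_count"],
        }
        prof = ClonalProfile(
            sample_id=sid,
            frequencies=freqs,
            provenance=tuple(keys),
            meta=meta,
        )
        if prof.is_empty:
            warnings.warn(
                f"sample {sid!r} has zero reads after filtering; "
                "profile flagged empty and excluded from statistics",
                stacklevel=2,
            )
        profiles.append(prof)
    return profiles


def run_qc(
    matrix: BarcodeCountMatrix, cfg: QCConfig = QCConfig()
) -> tuple[list[ClonalProfile], QCReport]:
    """Full QC chain: depth filter -> replicate-support filter -> pooling."""
    filtered, report = filter_replicates_by_depth(matrix, cfg)
    if len(filtered.counts) == 0:
        return [], report
    supported = filter_barcodes_by_replicate_support(filtered, cfg)
    profiles = pool_and_normalize(supported)
    report.empty_profiles = [p.sample_id for p in profiles if p.is_empty]
    return profiles, report


# ---------------------------------------------------------------------------
# profile (de)serialization: long TSV, one row per (sample, barcode)


def profiles_to_frame(profiles: list[ClonalProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for bc, f in p.frequencies.items():
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "barcode_id": bc,
                    "frequency": f,
                    "mouse_id": p.meta.get("mouse_id", ""),
                    "tissue": p.meta.get("tissue", ""),
                    "timepoint": p.meta.get("timepoint", ""),
                    "sorted_cell_count": p.meta.get("sorted_cell_count", pd.NA),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "barcode_id",
            "frequency",
            "mouse_id",
            "tissue",
            "timepoint",
            "sorted_cell_count",
        ],
    )


def frame_to_profiles(df: pd.DataFrame) -> list[ClonalProfile]:
    profiles = []
    for sid, g in df.groupby("sample_id", sort=False):
        freqs = pd.Series(g["frequency"].to_numpy(), index=g["barcode_id"].to_numpy())
        first = g.iloc[0]
        meta = {
            "mouse_id": first.get("mouse_id", ""),
            "tissue": first.get("tissue", ""),
            "timepoint": first.get("timepoint", ""),
            "sorted_cell_count": first.get("sorted_cell_count", pd.NA),
        }
        profiles.append(ClonalProfile(sample_id=str(sid), frequencies=freqs, meta=meta))
    return profiles
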