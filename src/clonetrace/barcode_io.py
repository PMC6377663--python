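"""Amplicon demultiplexing and count-matrix I/O.

Reads of a fixed-structure barcode amplicon are split by sample index,
anchored on the constant flank, matched against a reference barcode
library, and tallied into a replicate x barcode count matrix.  The matrix
and its metadata round-trip through a plain TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AmpliconDesign",
    "BarcodeLibrary",
    "SampleSheet",
    "BarcodeCountMatrix",
    "parse_sample_sheet",
    "read_library",
    "write_library",
    "demultiplex_and_count",
    "persist_count_matrix",
    "read_count_matrix",
    "META_COLUMNS",
]

_DNA_RE = re.compile(r"^[ACGT]+$")

#: Metadata columns of a count-matrix row, in canonical order.
META_COLUMNS = [
    "sample_id",
    "index_sequence",
    "mouse_id",
    "tissue",
    "timepoint",
    "replicate_id",
    "run_id",
    "sorted_cell_count",
]

TIMEPOINTS = ("T1", "T2", "T3", "T4")

# Constant regions of the barcode PCR product.  The 5' flank is the
# library-side primer landing site; the 3' flank is the reverse complement
# of the bottom-strand primer as seen on the read.
DEFAULT_FLANK_5P = "TGCTGCCGTCAACTAGAACA"
DEFAULT_FLANK_3P = "TAAGCGCCTGATTCGAGATC"


@dataclass(frozen=True)
class AmpliconDesign:
    """Fixed layout of the barcode amplicon on a sequencing read.

    A read is expected to start with the sample index, followed by the 5'
    constant flank, the barcode itself and (if the read is long enough)
    the 3' constant flank.
    """

    index_length: int = 8
    flank_5p: str = DEFAULT_FLANK_5P
    flank_3p: str = DEFAULT_FLANK_3P
    barcode_length: int = 98
    product_length: int = 150

    def __post_init__(self) -> None:
        if self.index_length < 1:
            raise ValueError("index_length must be >= 1")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")
        for name in ("flank_5p", "flank_3p"):
            seq = getattr(self, name)
            if not seq or not _DNA_RE.match(seq):
                raise ValueError(f"{name} must be nonempty uppercase DNA over ACGT")

    @property
    def barcode_start(self) -> int:
        return self.index_length + len(self.flank_5p)

    @property
    def min_read_length(self) -> int:
        """Shortest read that still contains index, 5' flank and barcode."""
        return self.barcode_start + self.barcode_length


@dataclass(frozen=True)
class BarcodeLibrary:
    """Reference set of barcode sequences, id -> sequence."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("barcode library is empty")
        seqs = list(self.entries.values())
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"library sequences have mixed lengths: {sorted(lengths)}")
        if len(set(seqs)) != len(seqs):
            raise ValueError("library contains duplicate sequences")
        for bc_id, seq in self.entries.items():
            if not _DNA_RE.match(seq):
                raise ValueError(f"library entry {bc_id!r} is not uppercase DNA")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SampleSheet:
    """Validated replicate-level sample metadata.

    One row per (sample, technical replicate); ``rows`` has exactly the
    columns in :data:`META_COLUMNS`.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("no samples in sheet")
        dup = df.duplicated(subset=["index_sequence", "run_id"], keep=False)
        if dup.any():
            rows = df.loc[dup, ["sample_id", "index_sequence", "run_id"]]
            raise ValueError(
                "duplicate (index_sequence, run_id) pairs:\n" + rows.to_string()
            )
        bad_tp = set(df["timepoint"].unique()) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(
                f"unknown timepoint token(s) {sorted(bad_tp)}; expected one of {TIMEPOINTS}"
            )
        dup_rep = df.duplicated(subset=["sample_id", "replicate_id"], keep=False)
        if dup_rep.any():
            raise ValueError(
                "duplicate (sample_id, replicate_id):\n"
                + df.loc[dup_rep, ["sample_id", "replicate_id"]].to_string()
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.rows["sample_id"]))

    def replicate_groups(self) -> dict[str, pd.DataFrame]:
        """Rows grouped by sample_id (technical replicates of one sample)."""
        return {sid: g for sid, g in self.rows.groupby("sample_id", sort=False)}

    def row_keys(self) -> list[str]:
        return [
            f"{s}.{r}"
            for s, r in zip(self.rows["sample_id"], self.rows["replicate_id"])
        ]


@dataclass
class BarcodeCountMatrix:
    """Raw read counts per (replicate row, barcode) with row metadata.

    ``counts`` is integer valued with row index equal to ``meta``'s index
    (``"<sample_id>.<replicate_id>"`` keys); columns are barcode ids.
    Reads that could not be assigned are tallied separately per row in
    ``unassigned``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    unassigned: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the same row index")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        vals = self.counts.to_numpy()
        if vals.size and ((vals < 0).any() or not np.issubdtype(vals.dtype, np.integer)):
            raise ValueError("counts must be nonnegative integers")
        if self.unassigned is None:
            self.unassigned = pd.Series(0, index=self.counts.index, dtype=int)

    @property
    def barcode_ids(self) -> list[str]:
        return list(self.counts.columns)

    def row_totals(self) -> pd.Series:
        """Assigned reads per replicate row."""
        return self.counts.sum(axis=1)

    def sample_groups(self) -> dict[str, pd.Index]:
        return {
            sid: g.index for sid, g in self.meta.groupby("sample_id", sort=False)
        }

    def subset_rows(self, keys: pd.Index | list[str]) -> "BarcodeCountMatrix":
        return BarcodeCountMatrix(
            counts=self.counts.loc[keys].copy(),
            meta=self.meta.loc[keys].copy(),
            unassigned=self.unassigned.loc[keys].copy(),
        )

    def equals(self, other: "BarcodeCountMatrix") -> bool:
        return (
            self.counts.equals(other.counts)
            and self.meta.equals(other.meta)
            and self.unassigned.equals(other.unassigned)
        )


# ---------------------------------------------------------------------------
# sample sheet


def parse_sample_sheet(path: Union[str, Path]) -> SampleSheet:
    """Read and validate a TSV sample sheet.

    Required columns: sample_id, index_sequence, mouse_id, tissue,
    timepoint, replicate_id, run_id.  sorted_cell_count is optional and
    may be empty per row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no samples in {path}") from None
    if len(df) == 0:
        raise ValueError(f"no samples in {path}")
    if "sorted_cell_count" not in df.columns:
        df["sorted_cell_count"] = ""
    df["sorted_cell_count"] = pd.to_numeric(
        df["sorted_cell_count"].replace("", pd.NA), errors="raise"
    ).astype("Int64")
    df = df[[c for c in META_COLUMNS if c in df.columns]]
    return SampleSheet(rows=df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# barcode library I/O


def read_library(path: Union[str, Path]) -> BarcodeLibrary:
    """Read a barcode library from FASTA or a 2-column (id, seq) TSV."""
    path = Path(path)
    text_head = path.open().read(1)
    entries: dict[str, str] = {}
    if text_head == ">":
        for rec in SeqIO.parse(str(path), "fasta"):
            entries[rec.id] = str(rec.seq).upper()
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["id", "seq"], dtype=str)
        entries = dict(zip(df["id"], df["seq"].str.upper()))
    if len(entries) != sum(1 for _ in entries):
        raise ValueError("duplicate ids in library file")
    return BarcodeLibrary(entries=entries)


def write_library(library: BarcodeLibrary, path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(seq), id=bc_id, description="")
        for bc_id, seq in library.entries.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# demultiplexing


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _iter_fastq(handle: IO[str]) -> Iterator[tuple[int, str]]:
    """Yield (record_number, sequence) from a 4-line FASTQ stream."""
    record = 0
    while True:
        header = handle.readline()
        if not header:
            return
        if header.strip() == "":
            continue
        record += 1
        if not header.startswith("@"):
            raise ValueError(f"malformed FASTQ record {record}: header {header!r}")
        seq = handle.readline().strip().upper()
        plus = handle.readline()
        qual = handle.readline()
        if not plus.startswith("+") or not qual:
            raise ValueError(f"malformed FASTQ record {record}")
        yield record, seq


def demultiplex_and_count(
    reads: Union[str, Path, IO[str], Iterable[str]],
    design: AmpliconDesign,
    sheet: SampleSheet,
    library: BarcodeLibrary,
    max_mismatch: int = 2,
    *,
    index_rescue: bool = False,
    search_revcomp: bool = False,
    run_id: str | None = None,
) -> BarcodeCountMatrix:
    """Split reads by sample index and count barcode occurrences.

    Each read is assigned to at most one (replicate, barcode) cell.  A
    read fails, and is tallied as unassigned for its replicate (or
    globally if the index itself does not match), when: the index is not
    in the sheet, the 5' flank does not match exactly, or the barcode is
    not within ``max_mismatch`` Hamming distance of a unique library
    entry.  Ambiguous library matches (ties at minimal distance) are
    rejected.

    Parameters
    ----------
    index_rescue:
        Allow a unique 1-mismatch index match when no exact match exists.
    search_revcomp:
        Also try the reverse complement of each read.
    run_id:
        Restrict demultiplexing to one sequencing run's sheet rows; if
        None, index sequences must be unique across the whole sheet.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if library.barcode_length != design.barcode_length:
        raise ValueError(
            f"library barcode length {library.barcode_length} != design "
            f"barcode_length {design.barcode_length}"
        )

    rows = sheet.rows
    if run_id is not None:
        rows = rows[rows["run_id"] == run_id]
        if len(rows) == 0:
            raise ValueError(f"no sheet rows for run {run_id!r}")
    if rows["index_sequence"].duplicated().any():
        raise ValueError(
            "index sequences not unique across runs; pass run_id to disambiguate"
        )
    row_keys = [
        f"{s}.{r}" for s, r in zip(rows["sample_id"], rows["replicate_id"])
    ]
    index_to_row = dict(zip(rows["index_sequence"], row_keys))

    seq_to_id = {seq: bc_id for bc_id, seq in library.entries.items()}
    barcode_ids = library.ids
    lib_items = list(library.entries.items())

    counts = {key: dict.fromkeys(barcode_ids, 0) for key in row_keys}
    unassigned = dict.fromkeys(row_keys, 0)
    unassigned_no_index = 0

    close_handle = False
    if isinstance(reads, (str, Path)):
        handle = open(reads)
        close_handle = True
    else:
        handle = reads  # type: ignore[assignment]

    flank = design.flank_5p
    bc_start = design.barcode_start
    bc_end = bc_start + design.barcode_length
    idx_len = design.index_length

    def match_index(idx: str) -> str | None:
        key = index_to_row.get(idx)
        if key is not None or not index_rescue:
            return key
        hits = [k for i, k in index_to_row.items() if _hamming(idx, i) <= 1]
        return hits[0] if len(hits) == 1 else None

    def match_barcode(obs: str) -> str | None:
        bc_id = seq_to_id.get(obs)
        if bc_id is not None or max_mismatch == 0:
            return bc_id
        best_d, best_ids = max_mismatch + 1, []
        for cand_id, cand_seq in lib_items:
            d = _hamming(obs, cand_seq)
            if d < best_d:
                best_d, best_ids = d, [cand_id]
            elif d == best_d:
                best_ids.append(cand_id)
        if best_d <= max_mismatch and len(best_ids) == 1:
            return best_ids[0]
        return None  # no match, or ambiguous tie

    try:
        for _record, seq in _iter_fastq(handle):
            orientations = [seq]
            if search_revcomp:
                orientations.append(str(Seq(seq).reverse_complement()))
            assigned = False
            row_key_seen: str | None = None
            for oriented in orientations:
                if len(oriented) < design.min_read_length:
                    continue
                row_key = match_index(oriented[:idx_len])
                if row_key is None:
                    continue
                row_key_seen = row_key
                if oriented[idx_len:bc_start] != flank:
                    continue
                bc_id = match_barcode(oriented[bc_start:bc_end])
                if bc_id is None:
                    continue
                counts[row_key][bc_id] += 1
                assigned = True
                break
            if not assigned:
                if row_key_seen is not None:
                    unassigned[row_key_seen] += 1
                else:
                    unassigned_no_index += 1
    finally:
        if close_handle:
            handle.close()

    count_df = pd.DataFrame.from_dict(counts, orient="index", dtype=int)
    count_df = count_df.reindex(columns=barcode_ids, fill_value=0)
    count_df.index = pd.Index(row_keys, name="row_key")
    meta = rows.set_index(pd.Index(row_keys, name="row_key"))[META_COLUMNS]
    una = pd.Series(unassigned, dtype=int).reindex(row_keys)
    una.index.name = "row_key"
    una.attrs["no_index_match"] = unassigned_no_index
    return BarcodeCountMatrix(counts=count_df, meta=meta, unassigned=una)


# ---------------------------------------------------------------------------
# count-matrix persistence

_UNASSIGNED_COL = "_unassigned"


def persist_count_matrix(matrix: BarcodeCountMatrix, path: Union[str, Path]) -> None:
    """Write the matrix as TSV: metadata columns, then one column per barcode.

    Zero counts are written explicitly so that re-reading reproduces the
    matrix bit-exactly (round-trip identity).
    """
    out = matrix.meta.copy()
    out[_UNASSIGNED_COL] = matrix.unassigned
    out = pd.concat([out, matrix.counts], axis=1)
    out.index.name = "row_key"
    out.to_csv(path, sep="\t")


def read_count_matrix(path: Union[str, Path]) -> BarcodeCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="row_key", dtype={"row_key": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count matrix file missing metadata columns: {missing}")
    meta = df[META_COLUMNS].copy()
    for col in META_COLUMNS[:-1]:
        meta[col] = meta[col].astype(str)
    meta["sorted_cell_count"] = meta["sorted_cell_count"].astype("Int64")
    rest = df.drop(columns=META_COLUMNS)
    if _UNASSIGNED_COL in rest.columns:
        unassigned = rest[_UNASSIGNED_COL].astype(int)
        rest = rest.drop(columns=[_UNASSIGNED_COL])
    else:
        unassigned = pd.Series(0, index=df.index, dtype=int)
    counts = rest.astype(int)
    return BarcodeCountMatrix(counts=counts, meta=meta, unassigned=unassigned)
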