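import numpy as np
import pandas as pd
import pytest

from clonetrace.barcode_io import BarcodeCountMatrix
from clonetrace.qc_normalize import ClonalProfile


def make_profile(freqs: dict, sample_id="S", **meta) -> ClonalProfile:
    s = pd.Series(freqs, dtype=float)
    return ClonalProfile(sample_id=sample_id, frequencies=s / s.sum(), meta=meta)


def make_matrix(count_rows: dict, sample_meta: dict | None = None) -> BarcodeCountMatrix:
    """Build a count matrix from {'S1.rep1': {'B1': 10, ...}, ...}.

    sample_meta optionally maps sample_id -> dict of metadata overrides
    (tissue, run per replicate via 'runs' list, etc.).
    """
    keys = list(count_rows)
    counts = pd.DataFrame.from_dict(count_rows, orient="index").fillna(0).astype(int)
    counts.index = pd.Index(keys, name="row_key")
    meta_rows = []
    for i, key in enumerate(keys):
        sample_id, replicate_id = key.rsplit(".", 1)
        over = (sample_meta or {}).get(sample_id, {})
        meta_rows.append(
            {
                "sample_id": sample_id,
                "index_sequence": _idx(i),
                "mouse_id": over.get("mouse_id", "M1"),
                "tissue": over.get("tissue", "tumor"),
                "timepoint": over.get("timepoint", "T2"),
                "replicate_id": replicate_id,
                "run_id": over.get("run_by_rep", {}).get(replicate_id, "R1"),
                "sorted_cell_count": over.get("sorted_cell_count", pd.NA),
            }
        )
    meta = pd.DataFrame(meta_rows, index=counts.index)
    meta["sorted_cell_count"] = meta["sorted_cell_count"].astype("Int64")
    return BarcodeCountMatrix(counts=counts, meta=meta)


def _idx(i: int) -> str:
    bases = "ACGT"
    return "".join(bases[(i >> (2 * k)) & 3] for k in range(8))


def random_profile(rng: np.random.Generator, n: int, sample_id="S") -> ClonalProfile:
    w = rng.dirichlet(np.full(n, 0.5))
    w = np.clip(w, 1e-12, None)
    return make_profile(
        {f"B{i}": float(x) for i, x in enumerate(w)}, sample_id=sample_id
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
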