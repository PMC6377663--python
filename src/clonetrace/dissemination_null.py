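"""Proportional-shedding null model by multinomial subsampling.

A virtual distal sample is produced by drawing cells with replacement
from the primary-tumor frequency profile (sample size = cells sorted by
FACS).  Observed distal statistics are compared against the distribution
of the same statistics over many such virtual samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clone_metrics import biomass_representation
from .qc_normalize import ClonalProfile

__all__ = [
    "NullResult",
    "subsample_profile",
    "expected_detection_analytic",
    "null_comparison",
]

STATISTICS = ("n_clones", "biomass_representation", "log_correlation")


@dataclass
class NullResult:
    statistic: str
    observed: float
    null_values: np.ndarray
    null_mean: float
    null_sd: float
    p_value: float


def subsample_profile(
    tumor: ClonalProfile, n_cells: int, seed: int | np.random.Generator = 0
) -> ClonalProfile:
    """Multinomial draw of ``n_cells`` cells from the tumor profile.

    Sampling is with replacement, each barcode drawn with probability
    equal to its tumor frequency; the returned profile is the draw
    normalized to one.  Reproducible given the seed.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = tumor.frequencies.to_numpy()
    if n_cells == 0 or p.size == 0:
        return ClonalProfile(
            sample_id=f"{tumor.sample_id}:subsample",
            frequencies=pd.Series(dtype=float),
            meta=dict(tumor.meta),
        )
    draw = rng.multinomial(n_cells, p / p.sum())
    freqs = pd.Series(draw / n_cells, index=tumor.frequencies.index)
    return ClonalProfile(
        sample_id=f"{tumor.sample_id}:subsample",
        frequencies=freqs,
        meta=dict(tumor.meta),
    )


def expected_detection_analytic(tumor: ClonalProfile, n_cells: int) -> float:
    """Expected number of distinct clones in a multinomial draw.

    E[K] = sum_i (1 - (1 - p_i)^n_cells).
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    p = tumor.frequencies.to_numpy()
    return float((1.0 - (1.0 - p) ** n_cells).sum())


def _log_correlation(tumor_freqs: pd.Series, sample_freqs: pd.Series) -> float:
    """Pearson r of log10 frequencies over the shared barcode set."""
    shared = tumor_freqs.index.intersection(sample_freqs.index)
    if len(shared) < 3:
        return float("nan")
    x = np.log10(tumor_freqs.loc[shared].to_numpy())
    y = np.log10(sample_freqs.loc[shared].to_numpy())
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _empirical_p(observed: float, null_values: np.ndarray) -> float:
    """Two-sided empirical p with the (r+1)/(n+1) correction."""
    finite = null_values[np.isfinite(null_values)]
    n = finite.size
    if n == 0 or not np.isfinite(observed):
        return float("nan")
    p_low = (1 + (finite <= observed).sum()) / (n + 1)
    p_high = (1 + (finite >= observed).sum()) / (n + 1)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def null_comparison(
    tumor: ClonalProfile,
    observed_distal: ClonalProfile,
    n_cells: int,
    n_replicates: int = 1000,
    seed: int = 0,
) -> dict[str, NullResult]:
    """Compare an observed distal profile to the proportional-shedding null.

    For each statistic (clone count; biomass representation against the
    tumor; log10-frequency Pearson correlation with the tumor over shared
    barcodes) the observed value and the null distribution over
    ``n_replicates`` virtual samples of ``n_cells`` cells are computed,
    with an empirical two-sided p-value using the (r+1)/(n+1) estimator.
    """
    if n_cells is None or (isinstance(n_cells, float) and np.isnan(n_cells)):
        raise ValueError(
            f"sorted cell count missing for sample {observed_distal.sample_id!r}"
        )
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_replicates == 1:
        warnings.warn(
            "n_replicates=1 gives a degenerate empirical p-value", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    p = tumor.frequencies.to_numpy()
    p = p / p.sum()

    # vectorized null replicates: counts matrix (n_replicates x n_barcodes)
    draws = rng.multinomial(n_cells, p, size=n_replicates)
    detected = draws > 0
    null_n_clones = detected.sum(axis=1).astype(float)
    null_biomass = detected @ p

    # masked Pearson correlation for every replicate at once
    log_tumor = np.log10(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(detected, np.log10(draws / max(n_cells, 1)), 0.0)
        w = detected.astype(float)
        n = w.sum(axis=1)
        sx = w @ log_tumor
        sxx = w @ log_tumor**2
        sy = y.sum(axis=1)
        syy = (y**2).sum(axis=1)
        sxy = y @ log_tumor
        var_x = n * sxx - sx**2
        var_y = n * syy - sy**2
        null_logcorr = (n * sxy - sx * sy) / np.sqrt(var_x * var_y)
        null_logcorr[(n < 3) | (var_x <= 0) | (var_y <= 0)] = np.nan

    obs = {
        "n_clones": float(observed_distal.n_barcodes_detected),
        "biomass_representation": biomass_representation(tumor, observed_distal),
        "log_correlation": _log_correlation(
            tumor.frequencies, observed_distal.frequencies
        ),
    }
    nulls = {
        "n_clones": null_n_clones,
        "biomass_representation": null_biomass,
        "log_correlation": null_logcorr,
    }
    results = {}
    for name in STATISTICS:
        vals = nulls[name]
        finite = vals[np.isfinite(vals)]
        results[name] = NullResult(
            statistic=name,
            observed=obs[name],
            null_values=vals,
            null_mean=float(finite.mean()) if finite.size else float("nan"),
            null_sd=float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
            p_value=_empirical_p(obs[name], vals),
        )
    return results
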