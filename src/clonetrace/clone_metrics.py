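"""Clonal statistics and group comparisons on frequency profiles.

All statistics operate on :class:`~clonetrace.qc_normalize.ClonalProfile`
objects.  Log-scale scatter/regression uses base 10; Shannon diversity is
in nats.  No pseudocounts are used anywhere: log-scale operations are
restricted to barcodes detected in both tissues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .qc_normalize import ClonalProfile

__all__ = [
    "TissueComparison",
    "FoldChangeClass",
    "engraftment_summary",
    "cumulative_clone_distribution",
    "dispersion",
    "biomass_representation",
    "fold_change_classify",
    "diversity_indices",
    "shared_barcode_regression",
    "organ_overlap_counts",
    "group_comparison_tests",
    "estimate_tumor_cells",
    "single_integration_fraction",
]


@dataclass
class TissueComparison:
    """Paired log10 frequencies of two tissues over shared barcodes."""

    mouse_id: str
    tissue_a: str
    tissue_b: str
    shared_barcodes: set[str]
    a_only: set[str]
    b_only: set[str]
    log10_a: pd.Series
    log10_b: pd.Series
    slope: float | None = None
    intercept: float | None = None
    adj_r_squared: float | None = None
    f_pvalue: float | None = None

    @property
    def has_regression(self) -> bool:
        return self.slope is not None


@dataclass
class FoldChangeClass:
    barcode_id: str
    ratio: float
    label: str  # "over" | "under" | "proportional"


def engraftment_summary(profile: ClonalProfile, n_injected: int) -> dict:
    """Number of detected clones and fraction of injected cells engrafted."""
    if n_injected < 1:
        raise ValueError("n_injected must be >= 1")
    n_clones = profile.n_barcodes_detected
    return {"n_clones": n_clones, "efficiency": n_clones / n_injected}


def cumulative_clone_distribution(
    profiles: list[ClonalProfile],
) -> pd.DataFrame:
    """Pooled cumulative clone-size distribution.

    Returns a frame with columns ``frequency`` (ascending) and
    ``cumulative_fraction`` (fraction of pooled clones at or below that
    frequency; nondecreasing, ending at 1).
    """
    freqs = np.concatenate(
        [p.frequencies.to_numpy() for p in profiles if not p.is_empty]
        or [np.array([])]
    )
    if freqs.size == 0:
        raise ValueError("all profiles empty; cumulative distribution undefined")
    freqs = np.sort(freqs)
    cum = np.arange(1, freqs.size + 1) / freqs.size
    return pd.DataFrame({"frequency": freqs, "cumulative_fraction": cum})


def dispersion(piece_profiles: list[ClonalProfile]) -> pd.Series:
    """Fraction of tumor pieces in which each barcode is detected.

    Defined as (#pieces with nonzero frequency) / (#pieces), over the
    barcodes detected in at least one piece; values lie in (0, 1].
    """
    n_pieces = len(piece_profiles)
    if n_pieces < 2:
        raise ValueError("dispersion requires >= 2 tumor pieces")
    hits: dict[str, int] = {}
    for p in piece_profiles:
        for bc in p.frequencies.index:
            hits[bc] = hits.get(bc, 0) + 1
    return pd.Series({bc: k / n_pieces for bc, k in hits.items()}, dtype=float)


def biomass_representation(tumor: ClonalProfile, distal: ClonalProfile) -> float:
    """Sum of primary-tumor frequencies of clones shared with the distal tissue."""
    shared = tumor.frequencies.index.intersection(distal.frequencies.index)
    return float(tumor.frequencies.loc[shared].sum())


def fold_change_classify(
    tumor: ClonalProfile, distal: ClonalProfile, threshold: float = 10.0
) -> tuple[list[FoldChangeClass], dict[str, float]]:
    """Classify shared barcodes by distal/tumor frequency ratio.

    ``over`` if ratio > threshold, ``under`` if ratio < 1/threshold, else
    ``proportional``.  Returns the per-barcode classes and the class
    proportions over the shared set (empty and flagged if no overlap).
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    shared = tumor.frequencies.index.intersection(distal.frequencies.index)
    classes: list[FoldChangeClass] = []
    for bc in shared:
        ratio = float(distal.frequencies[bc] / tumor.frequencies[bc])
        if ratio > threshold:
            label = "over"
        elif ratio < 1.0 / threshold:
            label = "under"
        else:
            label = "proportional"
        classes.append(FoldChangeClass(barcode_id=bc, ratio=ratio, label=label))
    n = len(classes)
    proportions = {
        label: (sum(c.label == label for c in classes) / n if n else math.nan)
        for label in ("over", "under", "proportional")
    }
    return classes, proportions


def diversity_indices(profile: ClonalProfile, simpson_complement: bool = False) -> dict:
    """Shannon diversity (nats) and Simpson index of a profile.

    Simpson is the repeat probability sum(p^2); with
    ``simpson_complement=True`` it is reported as 1 - sum(p^2).
    """
    if profile.is_empty:
        raise ValueError("diversity undefined for an empty profile")
    p = profile.frequencies.to_numpy()
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((p**2).sum())
    if simpson_complement:
        simpson = 1.0 - simpson
    return {"shannon": shannon, "simpson": simpson}


def shared_barcode_regression(
    a: ClonalProfile, b: ClonalProfile
) -> TissueComparison:
    """OLS of log10 frequencies in B on A over barcodes detected in both.

    Barcodes present in only one tissue are reported separately and
    excluded from the fit.  With fewer than 3 shared barcodes the
    regression fields are left unset.
    """
    shared_idx = a.frequencies.index.intersection(b.frequencies.index)
    shared = set(shared_idx)
    comp = TissueComparison(
        mouse_id=str(a.meta.get("mouse_id", "")),
        tissue_a=str(a.meta.get("tissue", a.sample_id)),
        tissue_b=str(b.meta.get("tissue", b.sample_id)),
        shared_barcodes=shared,
        a_only=a.barcodes - shared,
        b_only=b.barcodes - shared,
        log10_a=np.log10(a.frequencies.loc[shared_idx]),
        log10_b=np.log10(b.frequencies.loc[shared_idx]),
    )
    if len(shared_idx) < 3:
        return comp
    x = sm.add_constant(comp.log10_a.to_numpy())
    fit = sm.OLS(comp.log10_b.to_numpy(), x).fit()
    comp.intercept = float(fit.params[0])
    comp.slope = float(fit.params[1])
    comp.adj_r_squared = float(fit.rsquared_adj)
    comp.f_pvalue = float(fit.f_pvalue)
    return comp


def organ_overlap_counts(
    profiles_by_tissue: dict[str, ClonalProfile], tumor_tissue: str
) -> tuple[pd.Series, dict[int, int], set[str]]:
    """Per tumor barcode, the number of non-tumor tissues where it is detected.

    Returns (per-barcode site counts, histogram {n_sites: n_barcodes},
    barcodes found in distal tissues but not the tumor).
    """
    if tumor_tissue not in profiles_by_tissue:
        raise ValueError(f"tumor tissue {tumor_tissue!r} not among profiles")
    tumor = profiles_by_tissue[tumor_tissue]
    others = {t: p for t, p in profiles_by_tissue.items() if t != tumor_tissue}
    counts = {
        bc: sum(bc in p.barcodes for p in others.values()) for bc in tumor.barcodes
    }
    series = pd.Series(counts, dtype=int)
    hist: dict[int, int] = (
        series.value_counts().sort_index().to_dict() if len(series) else {}
    )
    non_resident = set().union(*(p.barcodes for p in others.values())) - tumor.barcodes \
        if others else set()
    return series, hist, non_resident


def group_comparison_tests(
    group_a, group_b, mode: str = "welch_log"
) -> dict:
    """Two-sided comparison of two groups of scalar statistics.

    Modes: ``welch_log`` (Welch t-test on log-transformed values),
    ``wilcoxon`` (rank-sum with continuity correction), and
    ``ks_pairwise_mean`` where each group is a list of per-animal value
    vectors and the mean +/- SD of all inter-animal two-sample K-S
    p-values is reported.
    """
    if mode == "welch_log":
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("welch_log needs n >= 2 per group")
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("welch_log requires strictly positive values")
        t, p = stats.ttest_ind(np.log(a), np.log(b), equal_var=False)
        return {"statistic": float(t), "p": float(p)}
    if mode == "wilcoxon":
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("wilcoxon needs n >= 2 per group")
        res = stats.mannwhitneyu(a, b, use_continuity=True, alternative="two-sided")
        return {"statistic": float(res.statistic), "p": float(res.pvalue)}
    if mode == "ks_pairwise_mean":
        if len(group_a) < 2 and len(group_b) < 2:
            raise ValueError("ks_pairwise_mean needs >= 2 animals in a group")
        pvals = []
        for va in group_a:
            for vb in group_b:
                res = stats.ks_2samp(np.asarray(va), np.asarray(vb))
                pvals.append(res.pvalue)
        pvals = np.asarray(pvals)
        return {
            "statistic": float(pvals.mean()),
            "p": float(pvals.mean()),
            "p_sd": float(pvals.std(ddof=1)) if len(pvals) > 1 else 0.0,
            "pairwise_p": pvals.tolist(),
        }
    raise ValueError(f"unknown mode {mode!r}")


def estimate_tumor_cells(
    min_diameter: float, max_diameter: float, mass_mg: float | None = None
) -> dict:
    """Tumor volume from caliper diameters, and a cell-number estimate.

    volume = min^2 * max / 2 (mm^3); cells = mass_mg * 1e6 when a mass
    is supplied.
    """
    if min_diameter <= 0 or max_diameter <= 0:
        raise ValueError("diameters must be positive")
    if max_diameter < min_diameter:
        raise ValueError("max_diameter must be >= min_diameter")
    out = {"volume_mm3": min_diameter**2 * max_diameter / 2.0}
    if mass_mg is not None:
        out["cell_estimate"] = mass_mg * 1e6
    return out


def single_integration_fraction(transduced_fraction: float) -> float:
    """Fraction of transduced cells carrying exactly one integration.

    Integration events per cell are Poisson; the mean lambda is solved
    from P(>=1) = ``transduced_fraction`` and the probability of exactly
    one integration conditional on at least one is returned:
    lambda * exp(-lambda) / (1 - exp(-lambda)).
    """
    if not 0 < transduced_fraction < 1:
        raise ValueError("transduced_fraction must be in (0, 1)")
    lam = -math.log1p(-transduced_fraction)
    return lam * math.exp(-lam) / transduced_fraction
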