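"""Bin filtering, GC/mappability correction and log2 normalization.

Raw per-bin read counts carry multiplicative technical biases tracking GC
content and mappability.  The correction fits a smooth bias surface to the
log-scale counts by alternating one-dimensional local (lowess) regressions on
the two covariates — a backfitting realization of a joint two-covariate
smooth — divides it out, and median-centers the log2 ratios so the diploid
state sits on the 0-line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPPABILITY = 0.8
DEFAULT_SPAN = 0.65
DEFAULT_ITERATIONS = 2
MIN_FIT_BINS = 50

__all__ = [
    "CopyNumberProfile",
    "filter_bins",
    "loess_correct",
    "normalize_log2",
    "correct_profile",
]


@dataclass
class CopyNumberProfile:
    """Normalized log2 copy-number ratios for one sample.

    ``log2`` is NaN wherever ``usable`` is False; over usable bins the median
    log2 ratio is 0 by construction.
    """

    bins: pd.DataFrame
    log2: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.bins) == len(self.log2) == len(self.usable)):
            raise ValueError("profile arrays must match the bin table length")
        self.log2 = np.asarray(self.log2, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)


def _as_matrix(counts) -> np.ndarray:
    a = np.asarray(counts, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def filter_bins(
    counts,
    bins: pd.DataFrame,
    min_mappability: float = DEFAULT_MIN_MAPPABILITY,
) -> np.ndarray:
    """Usability mask: drop blacklisted, low-mappability and cohort-zero bins.

    ``counts`` is a vector or a bins x samples matrix; a bin with zero reads
    across every sample of the cohort is considered unmeasurable.
    """
    mat = _as_matrix(counts)
    if mat.shape[0] != len(bins):
        raise ValueError(
            f"counts have {mat.shape[0]} rows but bin table has {len(bins)}"
        )
    usable = (
        ~bins["blacklisted"].to_numpy(bool)
        & (bins["mappability"].to_numpy(float) >= min_mappability)
        & (mat.sum(axis=1) > 0)
    )
    return usable


def _median_smooth(y: np.ndarray, cov: np.ndarray, span: float) -> np.ndarray:
    """Local-quadratic smooth through per-stratum medians of one covariate.

    The covariate is cut into equal-count strata; the bias curve is a
    Savitzky-Golay (local quadratic) fit through the stratum medians with a
    window covering a ``span`` fraction of the strata, interpolated back to
    every bin.  Fitting medians rather than raw points keeps large
    copy-number blocks (which can occupy a third of the genome) from being
    absorbed into the bias curve; the quadratic order tracks the curvature
    of a unimodal GC bias that a local-linear fit flattens.
    """
    n = len(y)
    k = int(np.clip(n // 20, 5, 50))
    order = np.argsort(cov, kind="stable")
    edges = np.array_split(order, k)
    centers = np.array([cov[idx].mean() for idx in edges])
    medians = np.array([np.median(y[idx]) for idx in edges])
    window = int(np.clip(round(span * k) | 1, 5, k if k % 2 else k - 1))
    if len(medians) < 5:
        fitted = np.full_like(medians, medians.mean())
    else:
        fitted = savgol_filter(medians, window_length=window, polyorder=2,
                               mode="interp")
    return np.interp(cov, centers, fitted)


def _fit_log_bias(
    y: np.ndarray, gc: np.ndarray, mapp: np.ndarray, span: float, iterations: int
) -> np.ndarray:
    """Alternating backfit of mean-zero log2 bias on GC then mappability."""
    components = {"gc": np.zeros_like(y), "mappability": np.zeros_like(y)}
    covariates = {"gc": gc, "mappability": mapp}
    active = []
    for name, cov in covariates.items():
        if np.ptp(cov) < 1e-9:
            logger.warning("covariate %s is constant; skipping its correction", name)
        else:
            active.append(name)
    for _ in range(iterations):
        for name in active:
            partial = y - sum(components[o] for o in active if o != name)
            fit = _median_smooth(partial, covariates[name], span)
            components[name] = fit - fit.mean()
    return sum(components[name] for name in active) if active else np.zeros_like(y)


def loess_correct(
    counts,
    bins: pd.DataFrame,
    usable: np.ndarray | None = None,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ITERATIONS,
) -> np.ndarray:
    """Divide out the fitted GC/mappability bias from raw counts.

    The bias is fitted on log2 counts of usable, nonzero bins, exponentiated
    and normalized to mean 1 over those bins, then divided out; unusable bins
    pass through untouched.  Accepts a vector or bins x samples matrix and
    corrects each sample independently (columns share the usability mask).
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    mat = _as_matrix(counts)
    if mat.shape[0] != len(bins):
        raise ValueError("counts rows must match bin table length")
    if usable is None:
        usable = np.ones(len(bins), dtype=bool)
    usable = np.asarray(usable, dtype=bool)

    gc = bins["gc"].to_numpy(float)
    mapp = bins["mappability"].to_numpy(float)
    corrected = mat.astype(float).copy()
    for j in range(mat.shape[1]):
        col = mat[:, j]
        fit_mask = usable & (col > 0)
        if fit_mask.sum() < MIN_FIT_BINS:
            raise ValueError(
                f"need >= {MIN_FIT_BINS} usable nonzero bins to fit the correction, "
                f"got {int(fit_mask.sum())}"
            )
        y = np.log2(col[fit_mask])
        log_bias = _fit_log_bias(y, gc[fit_mask], mapp[fit_mask], span, iterations)
        bias = 2.0 ** log_bias
        bias /= bias.mean()
        corrected[fit_mask, j] = col[fit_mask] / bias
    return corrected[:, 0] if np.asarray(counts).ndim == 1 else corrected


def normalize_log2(corrected, bins: pd.DataFrame, usable: np.ndarray) -> CopyNumberProfile:
    """Median-centered log2 ratios: log2(count / median usable count).

    The median of usable log2 ratios is exactly 0 after centering.  Usable
    bins with a zero count are assigned the profile minimum minus 1 (a
    sentinel for a homozygous-deletion-like dropout) and logged.
    """
    col = np.asarray(corrected, dtype=float)
    if col.ndim != 1:
        raise ValueError("normalize_log2 expects one sample (1-D counts)")
    if col.shape[0] != len(bins):
        raise ValueError("corrected counts must match bin table length")
    usable = np.asarray(usable, dtype=bool)
    pos = usable & (col > 0)
    if not pos.any():
        raise ValueError("profile has no usable bins with positive counts")
    log2 = np.full(len(bins), np.nan)
    log2[pos] = np.log2(col[pos])
    log2[pos] -= np.median(log2[pos])
    zero_usable = usable & (col <= 0)
    if zero_usable.any():
        logger.warning(
            "%d usable bins have zero counts; set to profile minimum - 1",
            int(zero_usable.sum()),
        )
        log2[zero_usable] = np.nanmin(log2[pos]) - 1.0
    return CopyNumberProfile(bins=bins, log2=log2, usable=usable)


def diploid_baseline(profile: CopyNumberProfile) -> float:
    """Robust estimate of the diploid 0-line of a normalized profile.

    Median centering leaves a small offset when an appreciable fraction of
    the genome is aberrant: the profile median then sits in the tail of the
    diploid noise mode.  The median of per-chromosome medians is insensitive
    to a minority of aberrant chromosomes and locates the diploid level to
    within a fraction of the bin noise; subtract it from log2 ratios before
    reading deflections off the profile.
    """
    chroms = profile.bins["chrom"].to_numpy()
    meds = []
    for chrom in pd.unique(chroms):
        mask = (chroms == chrom) & profile.usable
        vals = profile.log2[mask]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            meds.append(np.median(vals))
    if not meds:
        raise ValueError("profile has no usable bins")
    return float(np.median(meds))


def correct_profile(
    counts,
    bins: pd.DataFrame,
    cohort_counts=None,
    min_mappability: float = DEFAULT_MIN_MAPPABILITY,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ITERATIONS,
) -> CopyNumberProfile:
    """Filter, correct and normalize one sample's raw counts in one call.

    ``cohort_counts`` (bins x samples), when given, determines the
    cohort-zero part of the usability mask; otherwise the sample itself does.
    """
    usable = filter_bins(
        counts if cohort_counts is None else cohort_counts, bins, min_mappability
    )
    corrected = loess_correct(np.asarray(counts), bins, usable, span, iterations)
    return normalize_log2(corrected, bins, usable)
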