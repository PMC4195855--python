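"""Spatial and temporal intratumoral heterogeneity of copy-number calls.

Samples of one patient — spatially distinct regions from the same surgery,
or an initial tumor paired with its recurrence — are compared on a shared
grid of reduced regions (maximal constant-call runs across the samples,
regions shorter than 5 Mbp excluded).  Each CNA, identified as a (region,
direction) pair, is then categorized: spatially as present in *all*
regions, in *some* (more than one but not all), or in exactly *one*;
temporally as *shared*, *initial_only* or *recurrence_only*.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

from .calling import CNARegion, GAIN, LOSS
from .survival import reduce_to_regions, region_call_matrix

logger = logging.getLogger(__name__)

MIN_REGION_BP = 5_000_000

SPATIAL_CATEGORIES = ("all", "some", "one")
TEMPORAL_CATEGORIES = ("initial_only", "shared", "recurrence_only")

__all__ = [
    "MIN_REGION_BP",
    "shared_grid",
    "classify_spatial",
    "classify_temporal",
    "summarize",
]


def shared_grid(
    calls,
    bins: pd.DataFrame,
    sample_ids=None,
    min_region_bp: int = MIN_REGION_BP,
) -> tuple[list[CNARegion], pd.DataFrame]:
    """Reduced common regions across a patient's samples, small ones dropped.

    ``calls`` is bins x samples discrete calls on usable bins.  Returns the
    region list (>= ``min_region_bp`` long) and the samples x regions call
    matrix on that grid.
    """
    mat = np.asarray(calls)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("shared_grid needs at least 2 samples")
    regions = reduce_to_regions(mat, bins)
    kept = [r for r in regions if r.length_bp >= min_region_bp]
    if not kept:
        return [], pd.DataFrame()
    grid_calls = region_call_matrix(mat, bins, kept, sample_ids=sample_ids)
    return kept, grid_calls


def _detected_cnas(grid_calls: pd.DataFrame):
    """(region label, direction) pairs detected in at least one sample."""
    for region in grid_calls.columns:
        col = grid_calls[region].to_numpy()
        for direction in (LOSS, GAIN):
            if (col == direction).any():
                yield region, direction, col == direction


def classify_spatial(grid_calls: pd.DataFrame) -> pd.DataFrame:
    """Categorize each CNA by how many spatial regions carry it.

    ``grid_calls`` is samples x regions on a shared grid (>= 2 samples).
    Returns one row per detected (region, direction) with the sample count
    and category all / some / one.  Invariant to sample ordering.
    """
    n = len(grid_calls)
    if n < 2:
        raise ValueError("spatial classification needs >= 2 samples")
    rows = []
    for region, direction, present in _detected_cnas(grid_calls):
        k = int(present.sum())
        category = "all" if k == n else ("one" if k == 1 else "some")
        rows.append(
            {
                "region": region,
                "direction": "loss" if direction == LOSS else "gain",
                "n_detected": k,
                "n_samples": n,
                "category": category,
            }
        )
    return pd.DataFrame(rows, columns=["region", "direction", "n_detected",
                                       "n_samples", "category"])


def classify_temporal(initial_calls, recurrence_calls) -> pd.DataFrame:
    """Categorize each CNA across an initial/recurrence pair on a shared grid.

    Inputs are call Series/vectors indexed by region label.  Returns one row
    per detected (region, direction) with category initial_only / shared /
    recurrence_only.
    """
    init = pd.Series(initial_calls)
    rec = pd.Series(recurrence_calls)
    if not init.index.equals(rec.index):
        raise ValueError("initial and recurrence calls must share the region grid")
    rows = []
    for region in init.index:
        for direction in (LOSS, GAIN):
            in_i = init[region] == direction
            in_r = rec[region] == direction
            if not (in_i or in_r):
                continue
            category = (
                "shared" if (in_i and in_r)
                else ("initial_only" if in_i else "recurrence_only")
            )
            rows.append(
                {
                    "region": region,
                    "direction": "loss" if direction == LOSS else "gain",
                    "category": category,
                }
            )
    return pd.DataFrame(rows, columns=["region", "direction", "category"])


def summarize(categories) -> pd.DataFrame:
    """Counts and percentages per category, rounded the way cohort reports print them.

    ``categories`` is an iterable of category labels (or a DataFrame with a
    ``category`` column).  Fractions sum to 1; percentages are rounded half
    away from zero to whole numbers, e.g. 84 of 124 -> 68%.
    """
    if isinstance(categories, pd.DataFrame):
        labels = list(categories["category"])
    else:
        labels = list(categories)
    if not labels:
        return pd.DataFrame(columns=["category", "count", "fraction", "percent"])
    counts = Counter(labels)
    total = len(labels)
    rows = []
    for cat, cnt in sorted(counts.items()):
        frac = cnt / total
        rows.append(
            {
                "category": cat,
                "count": cnt,
                "fraction": frac,
                "percent": int(np.floor(100.0 * frac + 0.5)),
            }
        )
    return pd.DataFrame(rows)
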