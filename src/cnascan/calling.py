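"""Segmentation, discrete calling and tumor-cell-fraction estimation.

Profiles are cut into constant-copy segments by recursive binary
segmentation with a within-chromosome permutation test.  Segment means are
converted to discrete calls (loss / normal / gain) with thresholds derived
from a diploid-baseline mixture model: an event at integer copy number c in
a fraction f of all cells shifts the log2 ratio to

    r = log2(1 + f (c - 2) / 2),

so the minimum detectable cell fraction fixes the calling thresholds, and
inverting the identity turns an observed deflection r back into a cell
fraction.  With f = 0.30 the single-copy thresholds round to the familiar
+0.20 (gain) / -0.23 (loss).  Anchoring a subclonal event's fraction on a
known clonal event (the 1p/19q co-deletion in oligodendroglial tumors)
cancels the unknown purity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .correction import CopyNumberProfile

logger = logging.getLogger(__name__)

DEFAULT_F_MIN = 0.30
DEFAULT_MIN_SEG_BINS = 3
DEFAULT_SEG_ALPHA = 0.01
DEFAULT_SEG_PERMUTATIONS = 100
DEFAULT_MIN_COVER = 0.90
#: Printed-precision thresholds as used for external SNP-array segment data.
PRINTED_THRESHOLDS = (0.20, -0.23)

LOSS, NORMAL, GAIN = -1, 0, 1

__all__ = [
    "Segment",
    "CNARegion",
    "FractionEstimate",
    "segment_profile",
    "calling_thresholds",
    "call_segments",
    "call_value",
    "estimate_cell_fraction",
    "anchored_fraction",
    "region_call",
    "bin_calls",
]


@dataclass(frozen=True)
class Segment:
    """A contiguous constant-copy interval of usable bins on one chromosome."""

    chrom: str
    start_bin: int  # global index into the bin table, inclusive
    end_bin: int
    start_bp: int  # 1-based inclusive
    end_bp: int
    mean_log2: float
    n_bins: int
    call: int | None = None  # -1 loss / 0 normal / +1 gain, set by call_segments

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class CNARegion:
    """A named genomic region, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FractionEstimate:
    """Estimated fraction of cells carrying an event.

    ``value`` is clipped to [0, 1]; ``raw`` is the unclipped inversion and
    ``consistent`` is False when it exceeds 1.05, i.e. the observed deflection
    is larger than the assumed copy number and purity can explain.
    """

    value: float
    raw: float
    consistent: bool


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _best_split(x: np.ndarray, min_len: int) -> tuple[int, float]:
    """Best split point by the two-sample t statistic; returns (k, t)."""
    n = len(x)
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    k = np.arange(min_len, n - min_len + 1)
    nl = k.astype(float)
    nr = n - nl
    sl = cs[k - 1]
    sr = cs[-1] - sl
    ml = sl / nl
    mr = sr / nr
    ssl = cs2[k - 1] - nl * ml**2
    ssr = (cs2[-1] - cs2[k - 1]) - nr * mr**2
    pooled = (ssl + ssr) / np.maximum(n - 2, 1)
    se = np.sqrt(np.maximum(pooled, 0.0) * (1.0 / nl + 1.0 / nr))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(ml - mr) / se
    t = np.where(se == 0, np.where(np.abs(ml - mr) > 0, np.inf, 0.0), t)
    i = int(np.argmax(t))
    return int(k[i]), float(t[i])


def _split_points(
    x: np.ndarray,
    alpha: float,
    min_len: int,
    n_perm: int,
    rng: np.random.Generator,
) -> list[int]:
    """Recursively accepted breakpoints (offsets into x), sorted."""
    n = len(x)
    if n < 2 * min_len:
        return []
    k, t_obs = _best_split(x, min_len)
    if not np.isfinite(t_obs):
        exceed = 0
    else:
        exceed = 0
        for _ in range(n_perm):
            xp = rng.permutation(x)
            _, t_perm = _best_split(xp, min_len)
            if t_perm >= t_obs - 1e-12:
                exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    if p >= alpha:
        return []
    left = _split_points(x[:k], alpha, min_len, n_perm, rng)
    right = _split_points(x[k:], alpha, min_len, n_perm, rng)
    return left + [k] + [k + r for r in right]


def segment_profile(
    profile: CopyNumberProfile,
    alpha: float = DEFAULT_SEG_ALPHA,
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
    n_perm: int = DEFAULT_SEG_PERMUTATIONS,
    seed: int | None = None,
) -> list[Segment]:
    """Recursive binary segmentation of one profile, chromosome by chromosome.

    At each step the candidate breakpoint maximizing the two-sample t
    statistic is tested by permuting bin values within the current stretch;
    the split is accepted at permutation p < ``alpha`` and recursion
    continues on both sides.  Segments never get shorter than
    ``min_seg_bins`` usable bins; a chromosome with too few usable bins
    yields a single segment.  Deterministic for a fixed seed.
    """
    if min_seg_bins < 3:
        raise ValueError("min_seg_bins must be >= 3")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    bins = profile.bins
    segments: list[Segment] = []
    chroms = bins["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        on = np.flatnonzero((chroms == chrom) & profile.usable)
        if len(on) == 0:
            continue
        x = profile.log2[on]
        if len(on) < min_seg_bins:
            logger.warning(
                "chromosome %s has %d usable bins (< %d); single segment",
                chrom, len(on), min_seg_bins,
            )
            cuts: list[int] = []
        else:
            cuts = _split_points(x, alpha, min_seg_bins, n_perm, rng)
        bounds = [0] + cuts + [len(on)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            idx = on[a:b]
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start_bin=int(idx[0]),
                    end_bin=int(idx[-1]),
                    start_bp=int(bins["start"].iloc[idx[0]]),
                    end_bp=int(bins["end"].iloc[idx[-1]]),
                    mean_log2=float(x[a:b].mean()),
                    n_bins=int(b - a),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# Thresholds and discrete calls
# ---------------------------------------------------------------------------

def calling_thresholds(
    f_min: float = DEFAULT_F_MIN,
    purity: float = 1.0,
    rounded: bool = False,
) -> tuple[float, float]:
    """(gain, loss) log2-ratio thresholds for the minimum detectable fraction.

    ``f_min`` is the smallest tumor-cell fraction an event may have and still
    be called; with specimen purity folded in, the effective whole-specimen
    fraction is ``f = f_min * purity`` and the single-copy thresholds are
    ``log2(1 + f/2)`` (gain, c = 3) and ``log2(1 - f/2)`` (loss, c = 1).
    ``rounded=True`` returns the two-decimal printed values instead
    (0.20 / -0.23 at the defaults).
    """
    if not 0.0 < f_min <= 1.0:
        raise ValueError("f_min must lie in (0, 1]")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    f = f_min * purity
    gain = math.log2(1.0 + f / 2.0)
    loss = math.log2(1.0 - f / 2.0)
    if rounded:
        return round(gain, 2), round(loss, 2)
    return gain, loss


def call_value(mean_log2: float, thresholds: tuple[float, float]) -> int:
    """Discrete call for one segment mean under strict-inequality thresholds."""
    gain_thr, loss_thr = thresholds
    if not (gain_thr > 0 > loss_thr):
        raise ValueError("thresholds must satisfy gain > 0 > loss")
    if mean_log2 > gain_thr:
        return GAIN
    if mean_log2 < loss_thr:
        return LOSS
    return NORMAL


def call_segments(
    segments: list[Segment], thresholds: tuple[float, float]
) -> list[Segment]:
    """Attach discrete calls to segments (strict > gain / < loss)."""
    return [replace(s, call=call_value(s.mean_log2, thresholds)) for s in segments]


# ---------------------------------------------------------------------------
# Cell-fraction estimation
# ---------------------------------------------------------------------------

def estimate_cell_fraction(
    r: float, copies: int = 1, purity: float = 1.0
) -> FractionEstimate:
    """Invert r = log2(1 + f (c-2)/2) for the tumor-cell fraction f.

    ``r`` is the observed log2 deflection, ``copies`` the assumed integer
    copy number in aberrant cells (single-copy by default), ``purity`` the
    tumor-cell content of the specimen.  The raw inversion is
    ``f = 2 (2^r - 1) / (c - 2) / purity``; values above 1.05 are flagged as
    inconsistent with the assumed model, and the returned value is clipped
    to [0, 1].
    """
    if copies == 2:
        raise ValueError("copies must differ from the diploid 2")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if (copies < 2 and r > 1e-12) or (copies > 2 and r < -1e-12):
        raise ValueError(
            f"log2 ratio {r:+.3f} is inconsistent in sign with copies={copies}"
        )
    raw = 2.0 * (2.0**r - 1.0) / (copies - 2.0) / purity
    consistent = raw <= 1.05
    if not consistent:
        logger.warning(
            "cell fraction %.3f exceeds 1.05: deflection larger than the model allows",
            raw,
        )
    return FractionEstimate(value=float(np.clip(raw, 0.0, 1.0)), raw=raw,
                            consistent=consistent)


def anchored_fraction(
    event_r: float,
    anchor_r: float,
    event_copies: int = 1,
    anchor_copies: int = 1,
) -> float:
    """Cell fraction of an event relative to a clonal anchor event.

    Both fractions are inverted at purity 1 and their ratio returned, so the
    unknown purity cancels: a marginal 10q deflection divided by the clonal
    1p/19q deflection gives the fraction of tumor cells carrying 10q loss.
    Returns NaN (with a warning) for an event with no deflection.
    """
    anchor = estimate_cell_fraction(anchor_r, anchor_copies, purity=1.0)
    if anchor.raw <= 0:
        raise ValueError("anchor event has zero estimated fraction")
    event = estimate_cell_fraction(event_r, event_copies, purity=1.0)
    if event.raw == 0:
        logger.warning("event deflection is zero; relative fraction undefined")
        return float("nan")
    return event.raw / anchor.raw


# ---------------------------------------------------------------------------
# Region-level calls
# ---------------------------------------------------------------------------

def region_call(
    segments: list[Segment],
    region: CNARegion,
    min_cover: float = DEFAULT_MIN_COVER,
) -> int:
    """Call a region from called segments by the coverage rule.

    The region is called loss (gain) when segments called loss (gain)
    jointly cover at least ``min_cover`` of its length — a whole-chromosome
    loss therefore covers and calls any distal region on that chromosome.
    If both directions exceed the cover (not expected in practice), loss
    takes precedence with a warning.
    """
    if not 0.0 < min_cover <= 1.0:
        raise ValueError("min_cover must lie in (0, 1]")
    on_chrom = [s for s in segments if s.chrom == region.chrom]
    if not on_chrom:
        raise ValueError(f"region chromosome {region.chrom!r} absent from profile")
    if region.end < min(s.start_bp for s in on_chrom) or region.start > max(
        s.end_bp for s in on_chrom
    ):
        raise ValueError(f"region {region.label} lies outside the profiled extent")
    cover = {LOSS: 0, GAIN: 0}
    for s in on_chrom:
        if s.call not in (LOSS, GAIN):
            continue
        overlap = min(s.end_bp, region.end) - max(s.start_bp, region.start) + 1
        if overlap > 0:
            cover[s.call] += overlap
    need = min_cover * region.length_bp
    loss_hit = cover[LOSS] >= need
    gain_hit = cover[GAIN] >= need
    if loss_hit and gain_hit:
        logger.warning("region %s covered by both loss and gain; calling loss", region.label)
        return LOSS
    if loss_hit:
        return LOSS
    if gain_hit:
        return GAIN
    return NORMAL


def bin_calls(segments: list[Segment], n_bins: int) -> np.ndarray:
    """Expand per-segment calls to a per-bin vector (NaN outside segments)."""
    out = np.full(n_bins, np.nan)
    for s in segments:
        if s.call is None:
            raise ValueError("segments must be called first (call_segments)")
        out[s.start_bin : s.end_bin + 1] = s.call
    return out
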