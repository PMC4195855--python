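"""Synthetic shallow-WGS cohorts with known copy-number ground truth.

Forward model for everything the pipeline consumes: a binned genome with
GC/mappability annotation, Poisson read counts generated from a clonal
architecture at a given tumor purity, exponential survival outcomes tied to
copy-number status, multi-region samples and paired initial/recurrent tumors
drawn from a shared clone structure.

The central quantity is the average copy number of a bin across all cells of
the specimen,

    m = 2 (1 - purity) + purity * sum_k prev_k * c_k,

where ``prev_k`` is the prevalence of clone ``k`` among tumor cells and
``c_k`` its integer copy number at the bin (2 where the clone carries no
event).  The expected normalized log2 read-count ratio of the bin is then
``log2(m / 2)``; for a single event carried by a fraction ``f`` of all cells
at ``c`` copies this reduces to ``log2(1 + f (c - 2) / 2)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BIN_COLUMNS = ["chrom", "start", "end", "gc", "mappability", "blacklisted"]

DEFAULT_BIN_WIDTH = 15_000
#: Tumor-cell content matching the histological selection rule used for
#: FFPE specimens (areas with more than 60% tumor cells are macrodissected).
DEFAULT_PURITY = 0.6
#: Baseline overall-survival median (months): 16.7 years, the group without
#: distal 10q loss.
DEFAULT_BASELINE_MEDIAN_MONTHS = 16.7 * 12.0

__all__ = [
    "BIN_COLUMNS",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_PURITY",
    "DEFAULT_BASELINE_MEDIAN_MONTHS",
    "CNAEvent",
    "Clone",
    "ClonalArchitecture",
    "SurvivalModel",
    "make_genome",
    "mean_copy_number",
    "expected_log2_ratio",
    "bias_field",
    "simulate_bin_counts",
    "simulate_survival",
    "simulate_region_cohort",
    "simulate_multiregion",
    "spatial_truth",
    "simulate_recurrence",
    "temporal_truth",
    "write_truth",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNAEvent:
    """A copy-number event: an interval held at ``copies`` in aberrant cells.

    Coordinates are 1-based inclusive base pairs. ``copies`` is the total
    integer copy number in cells carrying the event and must differ from the
    diploid 2 (0 or 1 for losses, >= 3 for gains).
    """

    chrom: str
    start: int
    end: int
    copies: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CNAEvent start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("CNAEvent start must be >= 1 (1-based inclusive)")
        if self.copies < 0 or self.copies == 2:
            raise ValueError("CNAEvent copies must be a non-negative integer != 2")


@dataclass(frozen=True)
class Clone:
    """A clone: an identifier, its events, and its prevalence among tumor cells."""

    id: str
    events: tuple[CNAEvent, ...]
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"Clone {self.id!r} prevalence outside [0, 1]")
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class ClonalArchitecture:
    """Clone composition of one sample at a given tumor purity.

    Clone prevalences are fractions of the *tumor* compartment and must sum
    to <= 1; the remainder are tumor cells carrying no event (copy-neutral).
    The fraction of all cells in the specimen bearing an event is
    ``purity * sum(prevalence of clones carrying it)``.
    """

    clones: tuple[Clone, ...]
    purity: float = DEFAULT_PURITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "clones", tuple(self.clones))
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0, 1]")
        total = sum(c.prevalence for c in self.clones)
        if total > 1.0 + 1e-9:
            raise ValueError(f"clone prevalences sum to {total:.3f} > 1")
        ids = [c.id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clone identifiers")

    def events(self) -> list[CNAEvent]:
        """All distinct events across clones, in clone order."""
        seen: dict[CNAEvent, None] = {}
        for clone in self.clones:
            for ev in clone.events:
                seen.setdefault(ev, None)
        return list(seen)

    def cell_fraction(self, event: CNAEvent) -> float:
        """Fraction of all specimen cells carrying ``event``."""
        prev = sum(c.prevalence for c in self.clones if event in c.events)
        return self.purity * prev


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential overall-survival model with multiplicative hazard ratios.

    ``hazard_ratios`` maps a status-column name (a boolean predicate on the
    patient, e.g. carrying distal 10q loss) to its hazard ratio; hazards
    multiply across applicable predicates.  ``censoring_rate`` sets an
    administrative follow-up horizon at the baseline survival quantile
    ``1 - censoring_rate``, so a baseline patient is censored with that
    probability in expectation.
    """

    baseline_median_months: float = DEFAULT_BASELINE_MEDIAN_MONTHS
    hazard_ratios: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_median_months <= 0:
            raise ValueError("baseline_median_months must be positive")
        for name, hr in self.hazard_ratios.items():
            if hr <= 0:
                raise ValueError(f"hazard ratio for {name!r} must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")

    @property
    def baseline_rate(self) -> float:
        return np.log(2.0) / self.baseline_median_months

    @property
    def horizon_months(self) -> float:
        """Administrative censoring horizon implied by ``censoring_rate``."""
        if self.censoring_rate == 0.0:
            return np.inf
        return -np.log(self.censoring_rate) / self.baseline_rate


# ---------------------------------------------------------------------------
# Genome backbone
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, n: int, window: int = 25) -> np.ndarray:
    """Standardized smooth spatial noise of length n (moving-average AR surrogate)."""
    if n == 1:
        return np.zeros(1)
    w = max(3, min(window, n))
    z = rng.standard_normal(n + w)
    kernel = np.ones(w) / w
    s = np.convolve(z, kernel, mode="valid")[:n]
    sd = s.std()
    return (s - s.mean()) / sd if sd > 0 else np.zeros(n)


def make_genome(
    n_chroms: int = 2,
    chrom_length_bp: int = 30_000_000,
    bin_width: int = DEFAULT_BIN_WIDTH,
    gc_profile: str = "smooth",
    blacklist_fraction: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build an annotated binned genome (the coordinate backbone).

    Chromosomes are labelled "1".."n" and tiled with ``bin_width`` bins
    (1-based inclusive coordinates); the last bin of a chromosome may be
    shorter.  GC content follows a smooth spatial process inside [0.3, 0.7]
    (or is flat 0.5 with ``gc_profile="flat"``), mappability a smooth process
    inside [0.5, 1], and a ``blacklist_fraction`` of bins is flagged as
    problematic.
    """
    if n_chroms <= 0:
        raise ValueError("n_chroms must be positive")
    if chrom_length_bp <= 0:
        raise ValueError("chrom_length_bp must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not 0.0 <= blacklist_fraction < 1.0:
        raise ValueError("blacklist_fraction must lie in [0, 1)")
    if gc_profile not in ("smooth", "flat"):
        raise ValueError("gc_profile must be 'smooth' or 'flat'")

    rng = np.random.default_rng(seed)
    frames = []
    for c in range(1, n_chroms + 1):
        starts = np.arange(1, chrom_length_bp + 1, bin_width, dtype=np.int64)
        ends = np.minimum(starts + bin_width - 1, chrom_length_bp)
        n = len(starts)
        if gc_profile == "flat":
            gc = np.full(n, 0.5)
        else:
            # slowly wandering isochore-like component plus fast bin-to-bin
            # variation, so every chromosome spans the full GC range
            field = 0.6 * _smooth_field(rng, n, window=8) + 0.8 * rng.standard_normal(n)
            gc = 0.5 + 0.18 * np.tanh(field)
        # most bins map nearly uniquely; ~10% form spatially clustered
        # low-mappability stretches reaching down to 0.5
        mfield = 0.8 * _smooth_field(rng, n, window=12) + 0.6 * rng.standard_normal(n)
        u = (np.argsort(np.argsort(mfield)) + 0.5) / n
        mapp = np.where(
            u < 0.9, 1.0 - 0.1 * (u / 0.9), 0.9 - 0.4 * ((u - 0.9) / 0.1)
        )
        black = rng.random(n) < blacklist_fraction
        frames.append(
            pd.DataFrame(
                {
                    "chrom": str(c),
                    "start": starts,
                    "end": ends,
                    "gc": gc,
                    "mappability": mapp,
                    "blacklisted": black,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Read counts from a clonal architecture
# ---------------------------------------------------------------------------

def _event_bin_mask(bins: pd.DataFrame, event: CNAEvent, strict: bool = True) -> np.ndarray:
    """Boolean mask of bins covered by the event; checks grid alignment."""
    on_chrom = bins["chrom"].to_numpy() == event.chrom
    if strict and not on_chrom.any():
        raise ValueError(f"event chromosome {event.chrom!r} not present in bins")
    mask = on_chrom & (bins["start"].to_numpy() >= event.start) & (
        bins["end"].to_numpy() <= event.end
    )
    if strict:
        chrom_bins = bins.loc[on_chrom]
        if event.end > int(chrom_bins["end"].max()):
            raise ValueError(
                f"event {event.chrom}:{event.start}-{event.end} extends past its chromosome"
            )
        starts = chrom_bins["start"].to_numpy()
        ends = chrom_bins["end"].to_numpy()
        if event.start not in starts or event.end not in ends:
            raise ValueError(
                f"event {event.chrom}:{event.start}-{event.end} is off the bin grid; "
                "event boundaries must coincide with bin boundaries"
            )
    return mask


def mean_copy_number(bins: pd.DataFrame, architecture: ClonalArchitecture) -> np.ndarray:
    """Average copy number m per bin across all cells of the specimen."""
    n = len(bins)
    tumor = np.full(n, 2.0)
    for clone in architecture.clones:
        for ev in clone.events:
            mask = _event_bin_mask(bins, ev)
            tumor[mask] += clone.prevalence * (ev.copies - 2.0)
    return 2.0 * (1.0 - architecture.purity) + architecture.purity * tumor


def expected_log2_ratio(f: float, copies: int) -> float:
    """Expected log2 ratio of an event at copy number ``copies`` in a cell
    fraction ``f`` of the whole specimen: log2(1 + f (c - 2) / 2)."""
    return float(np.log2(1.0 + f * (copies - 2.0) / 2.0))


def bias_field(
    bins: pd.DataFrame, gc_amplitude: float = 2.0, map_exponent: float = 1.0
) -> np.ndarray:
    """Multiplicative technical bias per bin, normalized to mean 1.

    Unimodal in GC (Gaussian bump peaking at GC 0.45, width 0.12) times a
    power of mappability; any smooth shape exercises the correction, this one
    mimics the usual PCR-efficiency dome.
    """
    gc = bins["gc"].to_numpy()
    mapp = bins["mappability"].to_numpy()
    raw = np.exp(-gc_amplitude * ((gc - 0.45) / 0.12) ** 2 / 2.0) * mapp**map_exponent
    return raw / raw.mean()


def simulate_bin_counts(
    bins: pd.DataFrame,
    architecture: ClonalArchitecture,
    mean_depth_per_bin: float = 100.0,
    seed: int | None = None,
    gc_amplitude: float = 0.0,
    map_exponent: float = 0.0,
    dispersion: float | None = None,
) -> np.ndarray:
    """Draw per-bin read counts for one sample.

    Counts are Poisson with mean ``depth * bias(gc, mappability) * m / 2``;
    with ``dispersion`` a > 0 a gamma-Poisson (negative binomial) mixture of
    the same mean and variance ``mu + dispersion * mu^2`` is used instead.
    Bias defaults to flat (amplitude/exponent 0).
    """
    if mean_depth_per_bin <= 0:
        raise ValueError("mean_depth_per_bin must be positive")
    rng = np.random.default_rng(seed)
    m = mean_copy_number(bins, architecture)
    lam = mean_depth_per_bin * bias_field(bins, gc_amplitude, map_exponent) * m / 2.0
    if dispersion is None or dispersion == 0.0:
        return rng.poisson(lam)
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, lam / shape))


# ---------------------------------------------------------------------------
# Survival outcomes
# ---------------------------------------------------------------------------

def simulate_survival(
    status: pd.DataFrame,
    model: SurvivalModel,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate an overall-survival table from per-patient region status.

    ``status`` is indexed by patient id with one boolean column per predicate
    named in ``model.hazard_ratios`` (extra columns are ignored).  Event times
    are exponential with rate ``ln 2 / baseline_median * prod(applicable
    HRs)``; follow-up is administratively censored at the model horizon.
    Returns a DataFrame with columns id, time_months, event.
    """
    missing = [k for k in model.hazard_ratios if k not in status.columns]
    if missing:
        raise ValueError(f"status table lacks predicate columns: {missing}")
    rng = np.random.default_rng(seed)
    rate = np.full(len(status), model.baseline_rate)
    for name, hr in model.hazard_ratios.items():
        rate = rate * np.where(status[name].to_numpy(bool), hr, 1.0)
    t = rng.exponential(1.0 / rate)
    horizon = model.horizon_months
    event = (t <= horizon).astype(int)
    time = np.minimum(t, horizon)
    return pd.DataFrame(
        {"id": status.index.astype(str), "time_months": time, "event": event}
    ).reset_index(drop=True)


def simulate_region_cohort(
    n_patients: int,
    loss_prevalence: dict[str, float],
    hazard_ratios: dict[str, float] | None = None,
    baseline_median_months: float = DEFAULT_BASELINE_MEDIAN_MONTHS,
    censoring_rate: float = 0.45,
    exact_prevalence: bool = False,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-level cohort: a patients x regions call matrix plus survival.

    Each region in ``loss_prevalence`` is lost (call -1) independently per
    patient with the stated prevalence; with ``exact_prevalence`` the carrier
    count is fixed at round(prevalence * n) and only the carrier identities
    are random, matching the exact counts a cohort table reports.
    ``hazard_ratios`` ties survival to a subset of those regions.  The
    default censoring rate targets the roughly-half-deceased follow-up
    typical of a retrospective low-grade glioma discovery cohort.
    Returns ``(calls, survival)``.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    rng = np.random.default_rng(seed)
    ids = [f"P{i + 1:04d}" for i in range(n_patients)]
    calls = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    for region, prev in loss_prevalence.items():
        if not 0.0 <= prev <= 1.0:
            raise ValueError(f"prevalence for {region!r} outside [0, 1]")
        if exact_prevalence:
            col = np.zeros(n_patients, dtype=int)
            k = int(round(prev * n_patients))
            col[rng.choice(n_patients, size=k, replace=False)] = -1
            calls[region] = col
        else:
            calls[region] = np.where(rng.random(n_patients) < prev, -1, 0)
    model = SurvivalModel(
        baseline_median_months=baseline_median_months,
        hazard_ratios=dict(hazard_ratios or {}),
        censoring_rate=censoring_rate,
    )
    status = (calls == -1)
    survival = simulate_survival(status, model, seed=rng.integers(2**31))
    return calls, survival


# ---------------------------------------------------------------------------
# Multi-region and longitudinal samples
# ---------------------------------------------------------------------------

def simulate_multiregion(
    architecture: ClonalArchitecture,
    n_regions: int,
    mixing_noise: float = 0.05,
    seed: int | None = None,
    subclone_regions: dict[str, set[int]] | None = None,
) -> list[ClonalArchitecture]:
    """Spatially distinct same-surgery regions from one clone structure.

    The first clone is truncal and present in every region; every other clone
    is restricted to a subset of regions (given explicitly via
    ``subclone_regions`` as 0-based region indices, otherwise drawn at
    random, always a nonempty proper subset).  Prevalences are jittered by
    ``mixing_noise`` (truncated so sums stay within [0, 1]).
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if not architecture.clones:
        raise ValueError("architecture has no clones")
    if mixing_noise < 0:
        raise ValueError("mixing_noise must be non-negative")
    rng = np.random.default_rng(seed)
    truncal = architecture.clones[0]
    subclones = architecture.clones[1:]

    presence: dict[str, set[int]] = {}
    for clone in subclones:
        if subclone_regions and clone.id in subclone_regions:
            idx = set(subclone_regions[clone.id])
            if not idx or any(i < 0 or i >= n_regions for i in idx):
                raise ValueError(f"invalid region set for subclone {clone.id!r}")
        else:
            k = int(rng.integers(1, n_regions))  # nonempty proper subset
            idx = set(rng.choice(n_regions, size=k, replace=False).tolist())
        presence[clone.id] = idx

    regions = []
    for r in range(n_regions):
        new_clones = []
        prev = truncal.prevalence
        if mixing_noise > 0:
            prev = float(np.clip(prev + rng.normal(0, mixing_noise), 1e-3, 1.0))
        new_clones.append(replace(truncal, prevalence=prev))
        for clone in subclones:
            if r not in presence[clone.id]:
                continue
            p = clone.prevalence
            if mixing_noise > 0:
                p = float(np.clip(p + rng.normal(0, mixing_noise), 1e-3, 1.0))
            new_clones.append(replace(clone, prevalence=p))
        total = sum(c.prevalence for c in new_clones)
        if total > 1.0:
            new_clones = [replace(c, prevalence=c.prevalence / total) for c in new_clones]
        regions.append(
            ClonalArchitecture(clones=tuple(new_clones), purity=architecture.purity)
        )
    return regions


def spatial_truth(region_architectures: list[ClonalArchitecture]) -> dict[CNAEvent, str]:
    """Ground-truth spatial category per event: all / some / one region."""
    n = len(region_architectures)
    truth: dict[CNAEvent, str] = {}
    events: dict[CNAEvent, None] = {}
    for arch in region_architectures:
        for ev in arch.events():
            events.setdefault(ev, None)
    for ev in events:
        k = sum(1 for arch in region_architectures if arch.cell_fraction(ev) > 0)
        truth[ev] = "all" if k == n else ("one" if k == 1 else "some")
    return truth


def simulate_recurrence(
    initial: ClonalArchitecture,
    gained_events: list[CNAEvent] | tuple[CNAEvent, ...] = (),
    lost_clones: list[str] | tuple[str, ...] = (),
    gained_prevalence: float = 0.5,
    seed: int | None = None,
) -> tuple[ClonalArchitecture, ClonalArchitecture]:
    """Paired initial/recurrent architectures from one clone tree.

    The recurrence inherits the truncal clone, drops ``lost_clones`` (the
    truncal clone cannot be lost), and — if ``gained_events`` is nonempty —
    acquires a new clone carrying them at ``gained_prevalence`` of tumor
    cells, squeezing surviving subclones proportionally if needed.
    """
    if not initial.clones:
        raise ValueError("initial architecture has no clones")
    truncal_id = initial.clones[0].id
    known = {c.id for c in initial.clones}
    for cid in lost_clones:
        if cid not in known:
            raise ValueError(f"unknown clone to lose: {cid!r}")
        if cid == truncal_id:
            raise ValueError("the truncal clone cannot be lost in the recurrence")
    kept = [c for c in initial.clones if c.id not in set(lost_clones)]
    if gained_events:
        if not 0 < gained_prevalence <= 1:
            raise ValueError("gained_prevalence must lie in (0, 1]")
        # cap the new clone at the room left by the truncal clone, and squeeze
        # surviving subclones proportionally if needed
        gained_prev = min(gained_prevalence, 1.0 - kept[0].prevalence)
        if gained_prev <= 0:
            raise ValueError("truncal clone occupies the whole tumor; no room to gain")
        sub_total = sum(c.prevalence for c in kept[1:])
        room = 1.0 - kept[0].prevalence - gained_prev
        if sub_total > room and sub_total > 0:
            scale = room / sub_total
            kept = [kept[0]] + [replace(c, prevalence=c.prevalence * scale) for c in kept[1:]]
        kept.append(Clone("recurrence_gain", tuple(gained_events), gained_prev))
    recurrence = ClonalArchitecture(clones=tuple(kept), purity=initial.purity)
    return initial, recurrence


def temporal_truth(
    initial: ClonalArchitecture, recurrence: ClonalArchitecture
) -> dict[CNAEvent, str]:
    """Ground-truth temporal category per event across the pair."""
    truth: dict[CNAEvent, str] = {}
    events: dict[CNAEvent, None] = {}
    for arch in (initial, recurrence):
        for ev in arch.events():
            events.setdefault(ev, None)
    for ev in events:
        in_i = initial.cell_fraction(ev) > 0
        in_r = recurrence.cell_fraction(ev) > 0
        truth[ev] = "shared" if (in_i and in_r) else ("initial_only" if in_i else "recurrence_only")
    return truth


def write_truth(path, architecture_or_truth) -> None:
    """Serialize ground truth (architecture or category map) as a JSON sidecar."""
    def default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not serializable: {type(obj)}")

    if isinstance(architecture_or_truth, dict) and any(
        isinstance(k, CNAEvent) for k in architecture_or_truth
    ):
        payload = {
            f"{ev.chrom}:{ev.start}-{ev.end}:c{ev.copies}": cat
            for ev, cat in architecture_or_truth.items()
        }
    else:
        payload = architecture_or_truth
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
        fh.write("\n")
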