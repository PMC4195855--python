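"""Genome-wide permutation log-rank survival scan with region fusion.

Per candidate region, patients carrying the aberration are compared with the
rest of the cohort by a log-rank test whose significance is estimated by
permuting the (time, event) outcome pairs across patients — the call
structure within each patient stays intact.  Consecutive same-chromosome
regions individually significant at the fusion level are merged and
re-tested, and the final p-values are adjusted by Benjamini-Hochberg
(discovery) or Holm-Bonferroni (validation of a priori regions).  Effect
sizes are reported as Kaplan-Meier group medians and a one-covariate
proportional-hazards hazard ratio with a Wald 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import CNARegion, GAIN, LOSS

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA_FUSE = 0.05
DEFAULT_FUSED_COVER = 0.90

__all__ = [
    "CohortMatrix",
    "HazardRatio",
    "logrank",
    "permutation_p",
    "reduce_to_regions",
    "region_call_matrix",
    "scan",
    "validate",
    "stratify_four_groups",
    "km_median",
    "hazard_ratio",
    "bh_adjust",
    "holm_adjust",
]


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortMatrix:
    """Patients x regions discrete calls joined to overall survival.

    ``calls`` is indexed by patient id with one column per region label and
    values in {-1, 0, +1}; ``survival`` holds columns id, time_months, event.
    ``regions`` (optional) carries the genomic coordinates in genome order,
    needed for fusion.
    """

    calls: pd.DataFrame
    survival: pd.DataFrame
    regions: list[CNARegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        surv = self.survival
        for col in ("id", "time_months", "event"):
            if col not in surv.columns:
                raise ValueError(f"survival table lacks column {col!r}")
        if surv["id"].duplicated().any():
            raise ValueError("duplicate patient ids in survival table")
        if not set(surv["event"].unique()) <= {0, 1}:
            raise ValueError("event flag must be 0 or 1")
        ids = surv["id"].astype(str)
        calls = self.calls.copy()
        calls.index = calls.index.astype(str)
        missing = set(calls.index) - set(ids)
        if missing:
            raise ValueError(f"patients without survival: {sorted(missing)[:5]}")
        # align survival to the call matrix order; drop un-called patients
        surv = surv.set_index(ids).loc[calls.index]
        if calls.isna().any().any():
            raise ValueError("call matrix contains missing values")
        if self.regions:
            labels = [r.label for r in self.regions]
            if list(calls.columns) != labels:
                if set(labels) != set(calls.columns):
                    raise ValueError("region labels do not match call columns")
                calls = calls[labels]
        self.calls = calls
        self.times = surv["time_months"].to_numpy(float)
        self.events = surv["event"].to_numpy(int)


# ---------------------------------------------------------------------------
# Log-rank from first principles
# ---------------------------------------------------------------------------

def _logrank_chi2_many(
    times: np.ndarray, events: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Log-rank chi-square for each row of a boolean label matrix (P x n).

    Standard observed-minus-expected construction with hypergeometric
    variance at each distinct death time; all P label vectors share the one
    pass over death times, which is what makes permutation p-values cheap.
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    L = labels[:, order].astype(np.float64)
    n = len(t)
    # at-risk carriers just before position i = suffix sum of L
    suffix = np.cumsum(L[:, ::-1], axis=1)[:, ::-1]
    death_times = np.unique(t[e == 1])
    O1 = np.zeros(L.shape[0])
    E1 = np.zeros(L.shape[0])
    V = np.zeros(L.shape[0])
    for u in death_times:
        i0 = np.searchsorted(t, u, side="left")
        i1 = np.searchsorted(t, u, side="right")
        at_risk = n - i0
        dead = np.flatnonzero(e[i0:i1] == 1) + i0
        d = len(dead)
        n1 = suffix[:, i0]
        O1 += L[:, dead].sum(axis=1)
        frac = n1 / at_risk
        E1 += d * frac
        if at_risk > 1:
            V += d * frac * (1.0 - frac) * (at_risk - d) / (at_risk - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (O1 - E1) ** 2 / V
    return np.where(V > 0, chi2, 0.0)


def logrank(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, asymptotic p).

    ``group_labels`` is boolean/binary (True = carrier group).  Requires both
    groups nonempty and at least one event; a degenerate comparison with zero
    log-rank variance returns p = 1 with a warning.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g = np.asarray(group_labels).astype(bool)
    if times.shape != events.shape or times.shape != g.shape:
        raise ValueError("times, events and group labels must have equal length")
    if g.all() or not g.any():
        raise ValueError("log-rank test needs two nonempty groups")
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    chi2 = float(_logrank_chi2_many(times, events, g[None, :])[0])
    if chi2 == 0.0 and _zero_variance(times, events, g):
        logger.warning("log-rank variance is zero; returning p = 1")
        return 0.0, 1.0
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _zero_variance(times, events, g) -> bool:
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    gl = g[order]
    n = len(t)
    for u in np.unique(t[e == 1]):
        i0 = np.searchsorted(t, u, "left")
        n1 = gl[i0:].sum()
        at_risk = n - i0
        if 0 < n1 < at_risk:
            return False
    return True


def permutation_p(
    times,
    events,
    carrier,
    n_perm: int = DEFAULT_N_PERM,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation p for the log-rank statistic; returns (p, observed chi2).

    Outcome (time, event) pairs are permuted jointly across patients with
    the carrier labels held fixed — equivalently the labels are permuted —
    and p = (1 + #{perm chi2 >= observed}) / (n_perm + 1), never zero.
    A constant carrier vector yields p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    carrier = np.asarray(carrier).astype(bool)
    if carrier.all() or not carrier.any():
        logger.warning("constant carrier vector; permutation p = 1")
        return 1.0, 0.0
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = float(_logrank_chi2_many(times, events, carrier[None, :])[0])
    perms = rng.permuted(np.tile(carrier, (n_perm, 1)), axis=1)
    chi2 = _logrank_chi2_many(times, events, perms)
    p = (1.0 + np.count_nonzero(chi2 >= obs - 1e-12)) / (n_perm + 1.0)
    return float(p), obs


# ---------------------------------------------------------------------------
# Region reduction
# ---------------------------------------------------------------------------

def reduce_to_regions(calls, bins: pd.DataFrame) -> list[CNARegion]:
    """Collapse bins into maximal constant-call regions across samples.

    ``calls`` is a bins x samples array/DataFrame of discrete calls aligned
    to ``bins`` (which should already be restricted to usable bins); a new
    region starts wherever any sample's call changes or the chromosome does.
    """
    mat = np.asarray(calls)
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.shape[0] != len(bins):
        raise ValueError("calls rows must match bin table length")
    if len(bins) == 0:
        return []
    chroms = bins["chrom"].to_numpy()
    change = np.zeros(len(bins), dtype=bool)
    change[0] = True
    change[1:] = (chroms[1:] != chroms[:-1]) | (mat[1:] != mat[:-1]).any(axis=1)
    starts = np.flatnonzero(change)
    ends = np.r_[starts[1:] - 1, len(bins) - 1]
    return [
        CNARegion(
            chrom=str(chroms[a]),
            start=int(bins["start"].iloc[a]),
            end=int(bins["end"].iloc[b]),
        )
        for a, b in zip(starts, ends)
    ]


def region_call_matrix(calls, bins: pd.DataFrame, regions: list[CNARegion],
                       sample_ids=None) -> pd.DataFrame:
    """Per-sample call for each reduced region (constant within by design)."""
    mat = np.asarray(calls)
    if mat.ndim == 1:
        mat = mat[:, None]
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    rows = {}
    for region in regions:
        first = np.flatnonzero((chroms == region.chrom) & (starts == region.start))
        if len(first) == 0:
            raise ValueError(f"region {region.label} not on the bin grid")
        rows[region.label] = mat[first[0]]
    out = pd.DataFrame(rows)
    out.index = (
        pd.Index(sample_ids, name="patient_id")
        if sample_ids is not None
        else pd.RangeIndex(mat.shape[1])
    )
    return out


# ---------------------------------------------------------------------------
# Scan with fusion and multiple-testing adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR, discovery stage)."""
    p = np.asarray(pvalues, float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def holm_adjust(pvalues) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (validation stage)."""
    p = np.asarray(pvalues, float)
    if len(p) == 0:
        return p
    return multipletests(p, method="holm")[1]


def _direction_sign(direction: str) -> int:
    if direction == "loss":
        return LOSS
    if direction == "gain":
        return GAIN
    raise ValueError("direction must be 'loss' or 'gain'")


def _fused_carriers(
    calls: pd.DataFrame,
    members: list[CNARegion],
    sign: int,
    min_cover: float,
) -> np.ndarray:
    """Patient-level carrier status for a fused region: aberrant call on at
    least ``min_cover`` of the fused span, length-weighted."""
    lengths = np.array([r.length_bp for r in members], float)
    sub = (calls[[r.label for r in members]].to_numpy() == sign).astype(float)
    frac = (sub * lengths).sum(axis=1) / lengths.sum()
    return frac >= min_cover


def _result_row(cohort: CohortMatrix, region: CNARegion, carrier, p_raw, chi2,
                fused_id, n_members) -> dict:
    carrier = np.asarray(carrier, bool)
    hr = hazard_ratio(cohort.times, cohort.events, carrier)
    return {
        "region": region.label,
        "chrom": region.chrom,
        "start": region.start,
        "end": region.end,
        "n_fused": n_members,
        "fused_id": fused_id,
        "n_carriers": int(carrier.sum()),
        "n_patients": len(carrier),
        "statistic": chi2,
        "p_raw": p_raw,
        "hr": hr.hr,
        "ci_low": hr.ci_low,
        "ci_high": hr.ci_high,
        "median_carrier_months": km_median(cohort.times[carrier], cohort.events[carrier]),
        "median_rest_months": km_median(cohort.times[~carrier], cohort.events[~carrier]),
    }


def _scan_engine(
    cohort: CohortMatrix,
    direction: str,
    n_perm: int,
    alpha_fuse: float | None,
    adjust: str,
    seed,
    min_cover: float,
) -> pd.DataFrame:
    sign = _direction_sign(direction)
    # without coordinates each column stands alone (no fusion across columns)
    regions = cohort.regions or [
        CNARegion(str(c), 1, 1, label=str(c)) for c in cohort.calls.columns
    ]
    times, events = cohort.times, cohort.events

    tested: list[tuple[CNARegion, np.ndarray, float, float]] = []
    for i, region in enumerate(regions):
        carrier = (cohort.calls[region.label].to_numpy() == sign)
        if carrier.sum() < 2 or (~carrier).sum() < 2:
            logger.info("region %s skipped: fewer than 2 patients per group", region.label)
            continue
        rng = np.random.default_rng([seed if seed is not None else 0, i])
        p, chi2 = permutation_p(times, events, carrier, n_perm=n_perm, rng=rng)
        tested.append((region, carrier, p, chi2))

    rows: list[dict] = []
    if alpha_fuse is not None and tested:
        # fuse maximal runs of consecutive same-chromosome significant regions
        used = [False] * len(tested)
        i = 0
        fused_id = 0
        while i < len(tested):
            region, carrier, p, chi2 = tested[i]
            if p >= alpha_fuse:
                rows.append(_result_row(cohort, region, carrier, p, chi2, None, 1))
                i += 1
                continue
            j = i
            while (
                j + 1 < len(tested)
                and tested[j + 1][0].chrom == region.chrom
                and tested[j + 1][2] < alpha_fuse
            ):
                j += 1
            members = [tested[k][0] for k in range(i, j + 1)]
            if len(members) == 1:
                fused_region, fused_carrier = region, carrier
                p_f, chi2_f = p, chi2
            else:
                fused_region = CNARegion(
                    chrom=region.chrom,
                    start=min(r.start for r in members),
                    end=max(r.end for r in members),
                )
                fused_carrier = _fused_carriers(cohort.calls, members, sign, min_cover)
                if fused_carrier.sum() < 2 or (~fused_carrier).sum() < 2:
                    logger.info(
                        "fused region %s degenerate after re-calling; using union of carriers",
                        fused_region.label,
                    )
                    fused_carrier = np.any(
                        [tested[k][1] for k in range(i, j + 1)], axis=0
                    )
                rng = np.random.default_rng(
                    [seed if seed is not None else 0, 10_000 + fused_id]
                )
                p_f, chi2_f = permutation_p(times, events, fused_carrier,
                                            n_perm=n_perm, rng=rng)
            rows.append(
                _result_row(cohort, fused_region, fused_carrier, p_f, chi2_f,
                            fused_id, len(members))
            )
            fused_id += 1
            i = j + 1
    else:
        for region, carrier, p, chi2 in tested:
            rows.append(_result_row(cohort, region, carrier, p, chi2, None, 1))

    result = pd.DataFrame(rows)
    if len(result):
        adjuster = bh_adjust if adjust == "bh" else holm_adjust
        if adjust not in ("bh", "holm"):
            raise ValueError("adjust must be 'bh' or 'holm'")
        result["p_adjusted"] = adjuster(result["p_raw"].to_numpy())
    return result


def scan(
    cohort: CohortMatrix,
    direction: str = "loss",
    n_perm: int = DEFAULT_N_PERM,
    alpha_fuse: float = DEFAULT_ALPHA_FUSE,
    adjust: str = "bh",
    seed=None,
    min_cover: float = DEFAULT_FUSED_COVER,
) -> pd.DataFrame:
    """Discovery scan: permutation log-rank per region, fusion, BH adjustment.

    Each region contrasts carriers of the aberration (call equal to the scan
    direction) against the rest of the cohort.  Runs of consecutive
    same-chromosome regions with p < ``alpha_fuse`` are fused, re-called at
    the ``min_cover`` span-coverage rule and re-tested, then adjusted across
    the final region list.  Per-region permutation streams are derived from
    the master seed and the region index, so results are reproducible and
    order-independent.
    """
    return _scan_engine(cohort, direction, n_perm, alpha_fuse, adjust, seed, min_cover)


def validate(
    cohort: CohortMatrix,
    direction: str = "loss",
    n_perm: int = DEFAULT_N_PERM,
    adjust: str = "holm",
    seed=None,
) -> pd.DataFrame:
    """Validation scan of a-priori regions: no fusion, Holm adjustment."""
    return _scan_engine(cohort, direction, n_perm, None, adjust, seed,
                        DEFAULT_FUSED_COVER)


# ---------------------------------------------------------------------------
# Stratification and effect sizes
# ---------------------------------------------------------------------------

def stratify_four_groups(
    cohort: CohortMatrix,
    region_1p: str,
    region_19q: str,
    region_10q: str,
) -> pd.Series:
    """Label patients by 1p/19q co-deletion x distal 10q loss status.

    Co-deletion requires loss of both arms.  Labels are ``1p/19q-only``
    (favorable), ``10q-only`` (unfavorable), ``both`` and ``neither``.
    """
    calls = cohort.calls
    for col in (region_1p, region_19q, region_10q):
        if col not in calls.columns:
            raise ValueError(f"region {col!r} missing from call matrix")
    codel = (calls[region_1p] == LOSS) & (calls[region_19q] == LOSS)
    tenq = calls[region_10q] == LOSS
    labels = np.select(
        [codel & tenq, codel & ~tenq, ~codel & tenq],
        ["both", "1p/19q-only", "10q-only"],
        default="neither",
    )
    return pd.Series(labels, index=calls.index, name="group")


def km_median(times, events) -> float:
    """Kaplan-Meier median survival; NaN when the curve never reaches 0.5."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if len(times) == 0:
        raise ValueError("km_median needs at least one observation")
    km = KaplanMeierFitter().fit(times, events)
    med = km.median_survival_time_
    return float(med) if np.isfinite(med) else float("nan")


@dataclass(frozen=True)
class HazardRatio:
    """Hazard ratio with Wald 95% CI; ``converged`` False flags a monotone
    partial likelihood (one group's events all precede the other's), where
    the estimate diverges and the CI is unbounded."""

    hr: float
    ci_low: float
    ci_high: float
    converged: bool = True


def hazard_ratio(times, events, group_labels) -> HazardRatio:
    """One-covariate Cox proportional-hazards estimate by Newton iteration.

    Maximizes the Breslow partial likelihood for a binary covariate (carrier
    vs rest) and reports exp(beta) with a Wald 95% confidence interval.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(group_labels).astype(float)
    if x.max() == x.min():
        raise ValueError("hazard_ratio needs two groups")
    if events[x == 1].sum() < 1 or events[x == 0].sum() < 1:
        raise ValueError("hazard_ratio needs at least one event per group")

    order = np.argsort(times, kind="stable")
    t, e, xs = times[order], events[order], x[order]
    n = len(t)
    # suffix counts of carriers / all at risk at each distinct death time
    death_times = np.unique(t[e == 1])
    i0 = np.searchsorted(t, death_times, side="left")
    at_risk = (n - i0).astype(float)
    carriers_at_risk = np.cumsum(xs[::-1])[::-1]
    n1 = carriers_at_risk[i0]
    d = np.array([np.sum((t == u) & (e == 1)) for u in death_times], float)
    d1 = np.array([np.sum((t == u) & (e == 1) & (xs == 1)) for u in death_times], float)
    n0 = at_risk - n1

    beta = 0.0
    converged = False
    for _ in range(60):
        eb = np.exp(beta)
        denom = n0 + eb * n1
        mu = eb * n1 / denom  # expected carrier share of each death
        score = d1.sum() - (d * mu).sum()
        info = (d * mu * (1.0 - mu)).sum()
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(step) < 1e-10:
            converged = True
            break
    if not converged or abs(beta) > 15:
        logger.warning("monotone or non-converged partial likelihood; CI unbounded")
        return HazardRatio(float(np.exp(beta)), 0.0, float("inf"), converged=False)
    eb = np.exp(beta)
    denom = n0 + eb * n1
    mu = eb * n1 / denom
    se = 1.0 / np.sqrt((d * mu * (1.0 - mu)).sum())
    z = stats.norm.ppf(0.975)
    return HazardRatio(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
    )
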