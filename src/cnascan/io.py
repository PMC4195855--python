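"""File formats and run configuration.

Everything on disk is headered TSV with dot decimal separators.  Genomic
coordinates are 1-based inclusive internally and in our own TSV dialects;
BED input (0-based half-open) is converted at the boundary.  Segment tables
use the SEG shape distributed for TCGA level-3 copy-number data, with extra
columns tolerated on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import yaml

from .calling import CNARegion
from .synthetic import BIN_COLUMNS

logger = logging.getLogger(__name__)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_bins", "seg_mean"]
#: Header aliases accepted for external (TCGA-dialect) SEG files.
_SEG_ALIASES = {
    "sample": "sample", "id": "sample", "sample_id": "sample",
    "chrom": "chrom", "chromosome": "chrom", "chr": "chrom",
    "start": "start", "loc.start": "start",
    "end": "end", "loc.end": "end",
    "n_bins": "n_bins", "num_probes": "n_bins", "num.mark": "n_bins",
    "seg_mean": "seg_mean", "segment_mean": "seg_mean", "seg.mean": "seg_mean",
}

__all__ = [
    "RunConfig",
    "read_regions",
    "write_regions",
    "read_bins",
    "write_bins",
    "read_counts",
    "write_counts",
    "read_profiles",
    "write_profiles",
    "read_seg",
    "write_seg",
    "read_matrix",
    "write_matrix",
    "read_survival",
    "write_survival",
]


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults reproduce the published settings:
    15 kb bins, 30% minimum detectable tumor-cell fraction, 10,000
    permutations, fusion at p < 0.05, 5 Mbp minimum region, 90% overlap,
    BH adjustment for discovery."""

    seed: int = 0
    bin_width: int = 15_000
    f_min: float = 0.30
    thresholds_mode: str = "exact"  # or "printed"
    n_perm: int = 10_000
    alpha_fuse: float = 0.05
    min_region_bp: int = 5_000_000
    min_cover: float = 0.90
    adjust: str = "bh"  # or "holm"
    min_mappability: float = 0.8
    span: float = 0.65
    purity: float = 0.6

    def __post_init__(self) -> None:
        if self.thresholds_mode not in ("exact", "printed"):
            raise ValueError("thresholds_mode must be 'exact' or 'printed'")
        if self.adjust not in ("bh", "holm"):
            raise ValueError("adjust must be 'bh' or 'holm'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat key: value (YAML) mapping; unknown keys rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} is not a flat key: value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def read_regions(path, dialect: str = "bed") -> list[CNARegion]:
    """Read region definitions; ``dialect`` is "bed" (0-based half-open,
    headerless, chrom/start/end[/name]) or "table" (headered TSV with
    1-based inclusive chrom/start/end[/label] columns)."""
    regions: list[CNARegion] = []
    if dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
                chrom = parts[0].removeprefix("chr")
                try:
                    start0, end0 = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
                if start0 >= end0:
                    raise ValueError(f"{path}:{lineno}: start >= end")
                label = parts[3] if len(parts) > 3 and parts[3] else ""
                regions.append(CNARegion(chrom, start0 + 1, end0, label))
    elif dialect == "table":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        needed = {"chrom", "start", "end"}
        if not needed <= set(df.columns):
            raise ValueError(f"{path}: table dialect needs columns {sorted(needed)}")
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            if row.start > row.end:
                raise ValueError(f"{path}:{lineno}: start > end")
            label = getattr(row, "label", "") or ""
            regions.append(
                CNARegion(str(row.chrom).removeprefix("chr"),
                          int(row.start), int(row.end), str(label))
            )
    else:
        raise ValueError("dialect must be 'bed' or 'table'")
    return regions


def write_regions(path, regions: list[CNARegion]) -> None:
    pd.DataFrame(
        [
            {"chrom": r.chrom, "start": r.start, "end": r.end, "label": r.label}
            for r in regions
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bins, counts, profiles
# ---------------------------------------------------------------------------

def write_bins(path, bins: pd.DataFrame) -> None:
    """Bin annotation as headered TSV (1-based inclusive start/end)."""
    bins[BIN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bins(path) -> pd.DataFrame:
    bins = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(BIN_COLUMNS) - set(bins.columns)
    if missing:
        raise ValueError(f"{path}: bin table lacks columns {sorted(missing)}")
    bins["blacklisted"] = bins["blacklisted"].astype(bool)
    return bins[BIN_COLUMNS]


def write_counts(path, bins: pd.DataFrame, counts, sample_ids) -> None:
    """Bins x samples raw counts keyed by chrom/start/end."""
    mat = np.asarray(counts)
    if mat.ndim == 1:
        mat = mat[:, None]
    out = bins[["chrom", "start", "end"]].copy()
    for j, sid in enumerate(sample_ids):
        out[str(sid)] = mat[:, j]
    out.to_csv(path, sep="\t", index=False)


def read_counts(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Returns (coordinate frame, counts matrix, sample ids)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{path}: counts table lacks column {col!r}")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    if not samples:
        raise ValueError(f"{path}: counts table has no sample columns")
    return df[["chrom", "start", "end"]], df[samples].to_numpy(), samples


def write_profiles(path, bins: pd.DataFrame, log2_matrix, usable, sample_ids) -> None:
    """Normalized log2 ratios plus the shared usability mask column."""
    mat = np.asarray(log2_matrix, float)
    if mat.ndim == 1:
        mat = mat[:, None]
    out = bins[["chrom", "start", "end"]].copy()
    out["usable"] = np.asarray(usable, bool).astype(int)
    for j, sid in enumerate(sample_ids):
        out[str(sid)] = mat[:, j]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profiles(path) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end", "usable"):
        if col not in df.columns:
            raise ValueError(f"{path}: profile table lacks column {col!r}")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end", "usable")]
    return (
        df[["chrom", "start", "end"]],
        df[samples].to_numpy(float),
        df["usable"].to_numpy(bool),
        samples,
    )


# ---------------------------------------------------------------------------
# SEG tables
# ---------------------------------------------------------------------------

def write_seg(path, seg: pd.DataFrame) -> None:
    """Write a SEG table; requires the canonical columns, keeps extras."""
    missing = set(SEG_COLUMNS) - set(seg.columns)
    if missing:
        raise ValueError(f"SEG table lacks columns {sorted(missing)}")
    ordered = SEG_COLUMNS + [c for c in seg.columns if c not in SEG_COLUMNS]
    seg[ordered].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_seg(path) -> pd.DataFrame:
    """Read a SEG table, accepting the TCGA level-3 header dialect.

    Column names are matched case-insensitively against known aliases;
    unknown columns are preserved with a warning, "chr" prefixes stripped.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    extras = []
    for col in df.columns:
        alias = _SEG_ALIASES.get(col.strip().lower())
        if alias:
            rename[col] = alias
        else:
            extras.append(col)
    if extras:
        logger.warning("%s: passing through unrecognized SEG columns %s", path, extras)
    df = df.rename(columns=rename)
    missing = {"sample", "chrom", "start", "end", "seg_mean"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: SEG table lacks columns {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    if "n_bins" not in df.columns:
        df["n_bins"] = np.nan
    return df


def segments_to_seg(sample_id: str, segments) -> pd.DataFrame:
    """Flatten called Segment objects into SEG rows for one sample."""
    rows = []
    for s in segments:
        rows.append(
            {
                "sample": sample_id,
                "chrom": s.chrom,
                "start": s.start_bp,
                "end": s.end_bp,
                "n_bins": s.n_bins,
                "seg_mean": s.mean_log2,
                "call": s.call if s.call is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def seg_to_bin_calls(seg: pd.DataFrame, coords: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Expand per-segment calls onto a bin grid.

    ``coords`` has chrom/start/end per bin.  Returns a bins x samples call
    matrix (0 where no called segment covers a bin) and the sample order.
    """
    if "call" not in seg.columns:
        raise ValueError("SEG table has no call column; run calling first")
    samples = list(pd.unique(seg["sample"].astype(str)))
    chroms = coords["chrom"].to_numpy(str)
    starts = coords["start"].to_numpy()
    ends = coords["end"].to_numpy()
    mat = np.zeros((len(coords), len(samples)), dtype=int)
    for j, sid in enumerate(samples):
        sub = seg[seg["sample"].astype(str) == sid]
        for row in sub.itertuples(index=False):
            mask = (chroms == str(row.chrom)) & (starts >= row.start) & (ends <= row.end)
            mat[mask, j] = int(row.call)
    return mat, samples


# ---------------------------------------------------------------------------
# Call matrix and survival
# ---------------------------------------------------------------------------

def write_matrix(path, calls: pd.DataFrame) -> None:
    """Patients x regions discrete-call matrix (first column patient_id)."""
    calls.rename_axis("patient_id").to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: call matrix lacks a patient_id column")
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient ids")
    return df.set_index(df["patient_id"].astype(str)).drop(columns="patient_id")


def write_survival(path, survival: pd.DataFrame) -> None:
    survival[["id", "time_months", "event"]].to_csv(path, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = {"id", "time_months", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: survival table lacks columns {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient ids")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: event flag must be 0 or 1")
    if (df["time_months"] <= 0).any():
        raise ValueError(f"{path}: survival times must be positive")
    return df
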