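"""Readers and writers for on-disk study artifacts.

All coordinates are 0-based bin starts; a bin covers the half-open interval
``[start, start + resolution)``.  Peak intervals follow the BED convention
(0-based, half-open).  Contacts are strandless.

File dialects
-------------
bin-pair table
    TSV with header ``chr  bin1  bin2  count  fl  gc  ms  ip``.  One file per
    (sample, chromosome, pair class), or combined with an extra ``class``
    column.  ``fl``/``gc``/``ms``/``ip`` are pair-level covariates already on
    the log(x_i * x_j) scale.
bin-feature table
    TSV ``chr  bin_start  effective_length  gc  mappability  short_count``.
anchor list
    TSV ``chr  bin_start``.
score matrix
    TSV with sample identifiers as header row and first column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "CoordinateError",
    "StudyConfig",
    "SampleSpec",
    "AnchorSet",
    "PAIR_COLUMNS",
    "FEATURE_COLUMNS",
    "read_bin_pairs",
    "write_bin_pairs",
    "read_bin_features",
    "write_bin_features",
    "pair_covariates_from_features",
    "read_peaks_to_anchors",
    "union_anchors",
    "read_anchor_set",
    "write_anchor_set",
    "read_score_matrix",
    "write_score_matrix",
    "read_normalized_pairs",
    "write_normalized_pairs",
]


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


class CoordinateError(ValueError):
    """A genomic coordinate is inconsistent with the analysis resolution."""


#: column order of the bin-pair table dialect (on-disk header uses ``chr``/``bin1``/``bin2``)
PAIR_COLUMNS = ["chrom", "bin1", "bin2", "count", "fl", "gc", "ms", "ip"]
_PAIR_HEADER = ["chr", "bin1", "bin2", "count", "fl", "gc", "ms", "ip"]

FEATURE_COLUMNS = [
    "chrom",
    "bin_start",
    "effective_length",
    "gc",
    "mappability",
    "short_count",
]
_FEATURE_HEADER = ["chr", "bin_start", "effective_length", "gc", "mappability", "short_count"]

NORMALIZED_COLUMNS = [
    "chrom",
    "bin1",
    "bin2",
    "pair_class",
    "count",
    "fitted",
    "normalized",
]


@dataclass(frozen=True)
class SampleSpec:
    """Location of one sample's input files.

    ``tables`` is a directory containing ``<chrom>.and.tsv`` and
    ``<chrom>.xor.tsv`` bin-pair tables; ``peaks`` is the 1D ChIP-Seq peak
    file (BED/narrowPeak) defining the sample's anchor bins.
    """

    id: str
    tables: str
    peaks: str
    condition: str | None = None


@dataclass(frozen=True)
class StudyConfig:
    """Parameters shared by every step of a reproducibility study.

    Parameters
    ----------
    resolution
        Bin size in bp (typically 5000 or 10000).
    binning_distance
        Maximum anchor-to-bin genomic span retained in the data matrix, in
        bp.  The matrix width is ``m = 2 * binning_distance / resolution``.
    chromosomes
        Ordered chromosome names analysed.
    samples
        Sample specifications; identifiers must be unique.
    smoothing_d
        Window half-width for 1D smoothing, or ``"tune"`` to optimise it by
        subsampling.
    seed
        Master seed for every stochastic step.
    """

    resolution: int
    chromosomes: tuple[str, ...]
    samples: tuple[SampleSpec, ...] = ()
    binning_distance: int = 1_000_000
    smoothing_d: int | str = "tune"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.binning_distance <= 0 or self.binning_distance % self.resolution != 0:
            raise ValueError(
                "binning_distance must be a positive integer multiple of resolution"
            )
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample identifiers must be unique")
        if isinstance(self.smoothing_d, str):
            if self.smoothing_d != "tune":
                raise ValueError("smoothing_d must be a non-negative integer or 'tune'")
        elif self.smoothing_d < 0:
            raise ValueError("smoothing_d must be non-negative")
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        object.__setattr__(self, "samples", tuple(self.samples))

    @property
    def m(self) -> int:
        """Width of the anchor-by-offset matrix, ``2 * binning_distance / resolution``."""
        return 2 * self.binning_distance // self.resolution

    @property
    def n_strata(self) -> int:
        return self.m // 2


@dataclass
class AnchorSet:
    """Per-chromosome sorted, deduplicated anchor bin starts.

    Anchor bins are the fixed-size genomic bins overlapping a 1D ChIP-Seq
    peak of the targeted protein; the union of all samples' anchor sets
    defines the rows of the anchor-by-offset matrix.
    """

    resolution: int
    bins: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, starts in self.bins.items():
            arr = np.unique(np.asarray(starts, dtype=np.int64))
            if arr.size and np.any(arr % self.resolution != 0):
                raise CoordinateError(
                    f"anchor bin start on {chrom} is not a multiple of "
                    f"resolution {self.resolution}"
                )
            clean[chrom] = arr
        self.bins = clean

    @property
    def n_anchors(self) -> int:
        """Total number of anchor bins across chromosomes (N)."""
        return int(sum(a.size for a in self.bins.values()))

    def chrom_anchors(self, chrom: str) -> np.ndarray:
        return self.bins.get(chrom, np.empty(0, dtype=np.int64))

    def contains(self, chrom: str, starts: np.ndarray) -> np.ndarray:
        """Boolean membership of ``starts`` in this chromosome's anchors."""
        anchors = self.chrom_anchors(chrom)
        starts = np.asarray(starts, dtype=np.int64)
        if anchors.size == 0:
            return np.zeros(starts.shape, dtype=bool)
        idx = np.searchsorted(anchors, starts)
        idx = np.clip(idx, 0, anchors.size - 1)
        return anchors[idx] == starts

    def jaccard(self, other: "AnchorSet") -> float:
        """Intersection-over-union of the two genome-wide anchor sets."""
        chroms = set(self.bins) | set(other.bins)
        inter = 0
        for c in chroms:
            inter += np.intersect1d(
                self.chrom_anchors(c), other.chrom_anchors(c), assume_unique=True
            ).size
        union = self.n_anchors + other.n_anchors - inter
        return inter / union if union else float("nan")


def read_bin_pairs(
    path: str | Path, pair_class: str, resolution: int
) -> pd.DataFrame:
    """Read a bin-pair contact table.

    Rows with a zero count are dropped (only non-zero contacts are
    modelled), and the result is sorted by (chrom, bin1, bin2).  The
    returned frame carries an extra ``pair_class`` column.

    Raises
    ------
    ParseError
        Malformed header or non-numeric field (reported with line number).
    CoordinateError
        A bin start that is not a multiple of ``resolution``.
    ValueError
        A negative count.
    """
    if pair_class not in {"AND", "XOR"}:
        raise ValueError(f"pair_class must be 'AND' or 'XOR', got {pair_class!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if list(raw.columns) != _PAIR_HEADER:
        raise ParseError(
            f"{path}: expected header {_PAIR_HEADER}, found {list(raw.columns)}"
        )
    df = pd.DataFrame({"chrom": raw["chr"].astype(str)})
    for col in _PAIR_HEADER[1:]:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.index[numeric.isna()][0]) + 2  # +1 header, +1 1-based
            raise ParseError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col if col != "chr" else "chrom"] = numeric
    for col in ("bin1", "bin2", "count"):
        df[col] = df[col].astype(np.int64)
    for col in ("fl", "gc", "ms", "ip"):
        df[col] = df[col].astype(float)
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative count")
    for col in ("bin1", "bin2"):
        bad = df[col] % resolution != 0
        if bad.any():
            raise CoordinateError(
                f"{path}: {col}={int(df.loc[bad.idxmax(), col])} is not a "
                f"multiple of resolution {resolution}"
            )
    if not np.isfinite(df[["fl", "gc", "ms", "ip"]].to_numpy()).all():
        raise ValueError(f"{path}: non-finite covariate")
    df = df[df["count"] > 0]
    df = df.sort_values(["chrom", "bin1", "bin2"], kind="mergesort").reset_index(drop=True)
    df["pair_class"] = pair_class
    return df


def write_bin_pairs(df: pd.DataFrame, path: str | Path) -> None:
    out = df[PAIR_COLUMNS].rename(columns={"chrom": "chr"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bin_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _FEATURE_HEADER:
        raise ParseError(f"{path}: expected header {_FEATURE_HEADER}")
    df = df.rename(columns={"chr": "chrom"})
    vals = df[["effective_length", "gc", "mappability", "short_count"]].to_numpy()
    if not (np.isfinite(vals).all() and (vals > 0).all()):
        raise ValueError(f"{path}: bin features must be strictly positive and finite")
    if df.duplicated(["chrom", "bin_start"]).any():
        raise ValueError(f"{path}: duplicate (chrom, bin_start) row")
    return df


def write_bin_features(df: pd.DataFrame, path: str | Path) -> None:
    out = df[FEATURE_COLUMNS].rename(columns={"chrom": "chr"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def pair_covariates_from_features(
    pairs: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Attach pair-level covariates ``log(x_i * x_j)`` computed from per-bin features.

    Convenience path for tables that carry only (chrom, bin1, bin2, count).
    """
    feat = features.set_index(["chrom", "bin_start"])
    mapping = {
        "fl": "effective_length",
        "gc": "gc",
        "ms": "mappability",
        "ip": "short_count",
    }
    out = pairs.copy()
    idx1 = pd.MultiIndex.from_frame(pairs[["chrom", "bin1"]])
    idx2 = pd.MultiIndex.from_frame(pairs[["chrom", "bin2"]])
    for pair_col, feat_col in mapping.items():
        x1 = feat[feat_col].reindex(idx1).to_numpy()
        x2 = feat[feat_col].reindex(idx2).to_numpy()
        if np.isnan(x1).any() or np.isnan(x2).any():
            raise ValueError("bin pair references a bin absent from the feature table")
        out[pair_col] = np.log(x1 * x2)
    return out


def read_peaks_to_anchors(path: str | Path, resolution: int) -> AnchorSet:
    """Bin ChIP-Seq peak intervals to analysis resolution.

    Each peak ``[start, end)`` contributes every bin it overlaps: a peak
    spanning a bin boundary is assigned to all bins it spans.  Only the
    first three BED columns are consulted.
    """
    path = Path(path)
    bins: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: fewer than 3 fields at line {lineno}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer coordinate at line {lineno}") from exc
            if end <= start:
                raise ValueError(f"{path}: end <= start at line {lineno}")
            first = (start // resolution) * resolution
            last = ((end - 1) // resolution) * resolution
            bins.setdefault(chrom, []).extend(range(first, last + resolution, resolution))
    return AnchorSet(resolution, {c: np.array(v, dtype=np.int64) for c, v in bins.items()})


def union_anchors(anchor_sets: Sequence[AnchorSet]) -> AnchorSet:
    """Per-chromosome sorted union of anchor sets; its cardinality is the N of the data matrix."""
    if not anchor_sets:
        raise ValueError("union_anchors requires at least one anchor set")
    resolutions = {a.resolution for a in anchor_sets}
    if len(resolutions) != 1:
        raise ValueError(f"anchor sets at mixed resolutions: {sorted(resolutions)}")
    merged: dict[str, list[np.ndarray]] = {}
    for aset in anchor_sets:
        for chrom, arr in aset.bins.items():
            merged.setdefault(chrom, []).append(arr)
    return AnchorSet(
        resolutions.pop(),
        {c: np.unique(np.concatenate(arrs)) for c, arrs in merged.items()},
    )


def write_anchor_set(anchors: AnchorSet, path: str | Path) -> None:
    rows = [
        {"chr": chrom, "bin_start": int(b)}
        for chrom in sorted(anchors.bins)
        for b in anchors.bins[chrom]
    ]
    pd.DataFrame(rows, columns=["chr", "bin_start"]).to_csv(path, sep="\t", index=False)


def read_anchor_set(path: str | Path, resolution: int) -> AnchorSet:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["chr", "bin_start"]:
        raise ParseError(f"{path}: expected header ['chr', 'bin_start']")
    bins = {
        str(c): g["bin_start"].to_numpy(dtype=np.int64)
        for c, g in df.groupby("chr", sort=True)
    }
    return AnchorSet(resolution, bins)


def write_score_matrix(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a symmetric pairwise score matrix (sample IDs as header row/column)."""
    mat = scores.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or list(scores.index) != list(scores.columns):
        raise ValueError("score matrix must be square with matching sample labels")
    asym = np.nanmax(np.abs(mat - mat.T)) if mat.size else 0.0
    if asym > 1e-9:
        raise ValueError(f"score matrix asymmetric (max |S - S^T| = {asym:.3g})")
    scores.to_csv(path, sep="\t", float_format="%.6f", index_label="")


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: header row and first column disagree (missing header?)")
    return df


def write_normalized_pairs(df: pd.DataFrame, path: str | Path) -> None:
    out = df[NORMALIZED_COLUMNS].rename(columns={"chrom": "chr", "pair_class": "class"})
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_normalized_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["chr", "bin1", "bin2", "class", "count", "fitted", "normalized"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected header {expected}")
    return df.rename(columns={"chr": "chrom", "class": "pair_class"})
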