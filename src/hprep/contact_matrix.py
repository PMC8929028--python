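"""Anchor-by-offset contact matrices and 1D smoothing.

The core data structure is an N x m matrix: rows are the union anchor bins
of all samples in the study, columns are signed bin offsets
``{-m/2, ..., -1, +1, ..., +m/2}`` with ``m = 2 * binning_distance /
resolution`` (no offset-0 column).  Entry (i, j) holds the normalized
contact value between anchor i and the bin j bin-widths away; cells never
observed stay 0.

Smoothing is a 1D arithmetic mean over a sliding window of half-width d
along each row.  Windows are zero-padded past the matrix edge and the
divisor stays ``2d + 1``; the offset-0 gap is not a column, so offsets -1
and +1 are adjacent in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .io_formats import AnchorSet, StudyConfig

__all__ = ["AnchorOffsetMatrix", "build_matrix", "build_chrom_matrix", "smooth_matrix"]


@dataclass
class AnchorOffsetMatrix:
    """Normalized contacts for one chromosome, anchors x signed offsets."""

    chrom: str
    anchors: np.ndarray  # sorted union-anchor bin starts, length N
    resolution: int
    binning_distance: int
    values: np.ndarray  # N x m
    smoothed_with: int | None = None  # None = raw

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=np.int64)
        if self.values.shape != (self.anchors.size, self.m):
            raise ValueError(
                f"values shape {self.values.shape} != (N={self.anchors.size}, m={self.m})"
            )

    @property
    def m(self) -> int:
        return 2 * self.binning_distance // self.resolution

    @property
    def n_strata(self) -> int:
        return self.m // 2

    @property
    def offsets(self) -> np.ndarray:
        k = self.n_strata
        return np.concatenate([np.arange(-k, 0), np.arange(1, k + 1)])

    def column_of(self, offset: int) -> int:
        """Column index of a signed bin offset (offset 0 does not exist)."""
        k = self.n_strata
        if offset == 0 or abs(offset) > k:
            raise IndexError(f"offset {offset} outside +/-{k} (no offset-0 column)")
        return offset + k if offset < 0 else offset + k - 1

    def to_triplets(self) -> pd.DataFrame:
        """Sparse dump ``chr  anchor_start  offset  value`` of the nonzero cells."""
        rows, cols = np.nonzero(self.values)
        return pd.DataFrame(
            {
                "chr": self.chrom,
                "anchor_start": self.anchors[rows],
                "offset": self.offsets[cols],
                "value": self.values[rows, cols],
            }
        )


def build_chrom_matrix(
    normalized: pd.DataFrame,
    anchors: np.ndarray,
    chrom: str,
    resolution: int,
    binning_distance: int,
) -> AnchorOffsetMatrix:
    """Place one chromosome's normalized pairs onto the anchor-by-offset grid.

    Each pair end that is a union anchor receives the pair's value at the
    signed offset to the other end: an XOR pair populates one cell, an AND
    pair two (one per anchor row).  Pairs separated by more than
    ``binning_distance`` are dropped; a pair with neither end in the union
    anchor set is an error (it should have been NOT-classified upstream).
    """
    anchors = np.asarray(anchors, dtype=np.int64)
    n_strata = binning_distance // resolution
    m = 2 * n_strata
    values = np.zeros((anchors.size, m))
    mat = AnchorOffsetMatrix(chrom, anchors, resolution, binning_distance, values)
    if normalized.empty:
        return mat

    bin1 = normalized["bin1"].to_numpy(dtype=np.int64)
    bin2 = normalized["bin2"].to_numpy(dtype=np.int64)
    vals = normalized["normalized"].to_numpy(dtype=float)
    k = (bin2 - bin1) // resolution  # positive: bin2 downstream of bin1

    def locate(starts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(anchors, starts)
        idx_c = np.clip(idx, 0, max(anchors.size - 1, 0))
        member = anchors.size > 0
        is_anchor = (anchors[idx_c] == starts) if member else np.zeros(starts.shape, bool)
        return idx_c, is_anchor

    row1, is1 = locate(bin1)
    row2, is2 = locate(bin2)
    if not (is1 | is2).all():
        bad = int(np.argmin(is1 | is2))
        raise ValueError(
            f"{chrom}: pair ({bin1[bad]}, {bin2[bad]}) has no end in the union "
            "anchor set; NOT pairs must be excluded before matrix construction"
        )
    keep = k <= n_strata
    # end 1 is an anchor: other end sits at offset +k
    sel = keep & is1
    values[row1[sel], k[sel] + n_strata - 1] = vals[sel]
    # end 2 is an anchor: other end sits at offset -k
    sel = keep & is2
    values[row2[sel], n_strata - k[sel]] = vals[sel]
    return mat


def build_matrix(
    normalized: pd.DataFrame, union_anchors: AnchorSet, config: StudyConfig
) -> dict[str, AnchorOffsetMatrix]:
    """Build per-chromosome anchor-by-offset matrices for one sample.

    ``normalized`` is the sample's combined AND/XOR normalized pair table;
    rows are the union anchors so that matrices from different samples are
    directly comparable.
    """
    out = {}
    by_chrom = dict(tuple(normalized.groupby("chrom", sort=False)))
    for chrom in config.chromosomes:
        sub = by_chrom.get(
            chrom, pd.DataFrame(columns=["bin1", "bin2", "normalized"])
        )
        out[chrom] = build_chrom_matrix(
            sub,
            union_anchors.chrom_anchors(chrom),
            chrom,
            config.resolution,
            config.binning_distance,
        )
    return out


def smooth_matrix(mat: AnchorOffsetMatrix, d: int) -> AnchorOffsetMatrix:
    """Sliding-window row mean of half-width ``d`` (zero-padded, divisor 2d+1).

    ``d = 0`` is the identity.  The window runs over column indices, so the
    missing offset-0 column is skipped (offsets -1 and +1 are adjacent).
    """
    if d < 0:
        raise ValueError("smoothing half-width d must be non-negative")
    if d >= mat.m:
        raise ValueError(f"smoothing half-width d={d} must be < m={mat.m}")
    if d == 0:
        smoothed = mat.values.copy()
    else:
        # direct convolution (not a running sum) so all-zero windows stay
        # exactly zero for the later joint-zero removal
        kernel = np.full(2 * d + 1, 1.0 / (2 * d + 1))
        smoothed = convolve1d(mat.values, kernel, axis=1, mode="constant", cval=0.0)
    return replace(mat, values=smoothed, smoothed_with=d)
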