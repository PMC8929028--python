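"""Clustering-quality summaries of a reproducibility score matrix.

Pairwise scores are correlations, which are not ratio-scale, so before a
silhouette analysis they are standardized to [0, 1] by an affine min-max
map over the off-diagonal entries.  The silhouette here works directly on
similarities: for sample i in cluster A,

    s(i) = (a(i) - b(i)) / max(a(i), b(i)),

where a(i) is the mean similarity of i to the other members of A and b(i)
is the largest mean similarity of i to any rival cluster.  Good clustering
drives the average s(i) toward 1.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["minmax_scale", "silhouette_values", "silhouette_mean"]


def minmax_scale(scores: pd.DataFrame) -> pd.DataFrame:
    """Affine map of the off-diagonal scores onto [0, 1]; the diagonal is set to 1.

    Self-similarity is definitionally perfect, so diagonal entries are
    excluded from the min/max statistics to avoid anchoring the maximum.
    """
    mat = scores.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("score matrix must be square")
    off = ~np.eye(mat.shape[0], dtype=bool)
    lo, hi = mat[off].min(), mat[off].max()
    if hi <= lo:
        raise ValueError("constant score matrix cannot be min-max scaled")
    scaled = (mat - lo) / (hi - lo)
    np.fill_diagonal(scaled, 1.0)
    return pd.DataFrame(scaled, index=scores.index, columns=scores.columns)


def silhouette_values(
    scores: pd.DataFrame, labels: Mapping[str, str]
) -> pd.Series:
    """Per-sample silhouette values on a similarity matrix scaled to [0, 1].

    Samples in singleton clusters have no within-cluster similarity and
    get s(i) = 0 (flagged with a warning).
    """
    samples = list(scores.index)
    missing = [s for s in samples if s not in labels]
    if missing:
        raise ValueError(f"unlabeled samples: {missing}")
    clusters: dict[str, list[str]] = {}
    for s in samples:
        clusters.setdefault(labels[s], []).append(s)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least two clusters")
    sim = scores.to_numpy(dtype=float)
    idx = {s: i for i, s in enumerate(samples)}
    values = {}
    for s in samples:
        own = labels[s]
        mates = [m for m in clusters[own] if m != s]
        if not mates:
            warnings.warn(f"singleton cluster {own!r}: s({s}) set to 0", RuntimeWarning)
            values[s] = 0.0
            continue
        a = float(np.mean([sim[idx[s], idx[m]] for m in mates]))
        b = max(
            float(np.mean([sim[idx[s], idx[m]] for m in members]))
            for cl, members in clusters.items()
            if cl != own
        )
        values[s] = (a - b) / max(a, b) if max(a, b) > 0 else 0.0
    return pd.Series(values, name="silhouette")


def silhouette_mean(scores: pd.DataFrame, labels: Mapping[str, str]) -> float:
    """Average silhouette over all samples; closer to 1 means cleaner clustering."""
    return float(silhouette_values(scores, labels).mean())
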