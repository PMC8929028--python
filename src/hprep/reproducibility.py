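"""Distance-stratified weighted Pearson reproducibility scores.

Two samples' anchor-by-offset matrices (built on the shared union anchor
set, then smoothed) are compared stratum by stratum.  Stratum k pools the
columns at offsets -k and +k into paired vectors of length 2N; positions
that are zero in both samples are removed, leaving N_k values.  Per
stratum the score is the (population-moment) Pearson correlation r_k, and
strata are combined with weights

    w_k = N_k * sd(a'_k) * sd(b'_k) / sum_K N_k * sd(a'_k) * sd(b'_k)

so larger and more variable strata carry more weight.  The reproducibility
score ``sum_k r_k w_k`` lies in [-1, 1] and reads like a correlation.

A stratum with N_k < 2 or zero variance in either vector is undefined: it
gets weight 0 and is excluded from the weight denominator.  Genome-level
scores are unweighted arithmetic means over chromosomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contact_matrix import AnchorOffsetMatrix, smooth_matrix

__all__ = [
    "StratumPair",
    "GenomeScore",
    "ScoreMatrix",
    "extract_stratum",
    "stratum_correlation",
    "stratum_weights",
    "reproducibility_score",
    "genome_score",
    "score_matrix",
    "tune_smoothing",
    "naive_pearson",
]


@dataclass
class StratumPair:
    """Paired stratum-k vectors from two samples after joint-zero removal."""

    k: int
    a: np.ndarray
    b: np.ndarray

    @property
    def n(self) -> int:
        return self.a.size

    @property
    def defined(self) -> bool:
        """A correlation exists: >= 2 positions and nonzero variance in both vectors."""
        return (
            self.n >= 2
            and bool(np.ptp(self.a) > 0)
            and bool(np.ptp(self.b) > 0)
        )


def extract_stratum(
    mat_a: AnchorOffsetMatrix, mat_b: AnchorOffsetMatrix, k: int
) -> StratumPair:
    """Pool the +/-k offset columns of both matrices and drop joint-zero positions."""
    if mat_a.anchors.size != mat_b.anchors.size or not np.array_equal(
        mat_a.anchors, mat_b.anchors
    ):
        raise ValueError(
            "matrices were not built on the same (union) anchor set; rebuild both "
            "on the union of all samples' anchors"
        )
    cols = [mat_a.column_of(-k), mat_a.column_of(+k)]
    a = mat_a.values[:, cols].T.ravel()
    b = mat_b.values[:, cols].T.ravel()
    keep = (a != 0) | (b != 0)
    return StratumPair(k=k, a=a[keep], b=b[keep])


def _population_sd(x: np.ndarray) -> float:
    var = float(np.mean(x * x) - np.mean(x) ** 2)
    return math.sqrt(max(var, 0.0))


def stratum_correlation(s: StratumPair) -> float:
    """Pearson correlation of the stratum's paired vectors; NaN if undefined."""
    if not s.defined:
        return float("nan")
    a = s.a - s.a.mean()
    b = s.b - s.b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def stratum_weights(strata: list[StratumPair]) -> np.ndarray:
    """Normalized weights ``N_k * sd(a'_k) * sd(b'_k)``; 0 for undefined strata.

    Standard deviations are population (1/N_k) moments.  Undefined strata
    are excluded from the denominator so defined weights still sum to 1.
    """
    raw = np.zeros(len(strata))
    for i, s in enumerate(strata):
        if s.defined:
            raw[i] = s.n * _population_sd(s.a) * _population_sd(s.b)
    total = raw.sum()
    if total == 0.0:
        raise ValueError("every stratum is undefined; no score can be formed")
    return raw / total


def reproducibility_score(
    mat_a: AnchorOffsetMatrix, mat_b: AnchorOffsetMatrix, d: int = 0
) -> float:
    """Weighted stratified correlation between two samples on one chromosome.

    Both matrices are smoothed with half-width ``d`` before stratification.
    Returns NaN when no stratum is defined.
    """
    sa = smooth_matrix(mat_a, d)
    sb = smooth_matrix(mat_b, d)
    strata = [extract_stratum(sa, sb, k) for k in range(1, sa.n_strata + 1)]
    try:
        w = stratum_weights(strata)
    except ValueError:
        return float("nan")
    score = 0.0
    for wk, s in zip(w, strata):
        if wk > 0.0:
            score += wk * stratum_correlation(s)
    return float(np.clip(score, -1.0, 1.0))


@dataclass
class GenomeScore:
    """Per-chromosome scores plus their across-chromosome mean and SD."""

    per_chrom: dict[str, float]

    @property
    def defined(self) -> dict[str, float]:
        return {c: v for c, v in self.per_chrom.items() if not math.isnan(v)}

    @property
    def mean(self) -> float:
        vals = list(self.defined.values())
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd(self) -> float:
        vals = list(self.defined.values())
        return float(np.std(vals)) if vals else float("nan")


def genome_score(
    mats_a: dict[str, AnchorOffsetMatrix],
    mats_b: dict[str, AnchorOffsetMatrix],
    d: int = 0,
) -> GenomeScore:
    """Score every shared chromosome; aggregate as an unweighted arithmetic mean."""
    chroms = [c for c in mats_a if c in mats_b]
    if not chroms:
        raise ValueError("samples share no chromosome")
    per = {c: reproducibility_score(mats_a[c], mats_b[c], d) for c in chroms}
    if all(math.isnan(v) for v in per.values()):
        warnings.warn("no chromosome yielded a defined score", RuntimeWarning)
    elif any(math.isnan(v) for v in per.values()):
        bad = [c for c, v in per.items() if math.isnan(v)]
        warnings.warn(f"undefined score on {bad}; mean taken over the rest", RuntimeWarning)
    return GenomeScore(per)


@dataclass
class ScoreMatrix:
    """Symmetric pairwise reproducibility scores for a whole study."""

    samples: list[str]
    per_chrom: dict[str, pd.DataFrame]
    mean: pd.DataFrame
    sd: pd.DataFrame


def score_matrix(
    study_mats: dict[str, dict[str, AnchorOffsetMatrix]], d: int = 0
) -> ScoreMatrix:
    """All pairwise genome scores among samples (S*(S-1)/2 comparisons)."""
    samples = list(study_mats)
    chroms = list(next(iter(study_mats.values())))
    grids = {c: pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples) for c in chroms}
    mean = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    sd = pd.DataFrame(np.zeros((len(samples), len(samples))), index=samples, columns=samples)
    for i, si in enumerate(samples):
        for sj in samples[i + 1 :]:
            gs = genome_score(study_mats[si], study_mats[sj], d)
            for c in chroms:
                grids[c].loc[si, sj] = grids[c].loc[sj, si] = gs.per_chrom[c]
            mean.loc[si, sj] = mean.loc[sj, si] = gs.mean
            sd.loc[si, sj] = sd.loc[sj, si] = gs.sd
    return ScoreMatrix(samples, grids, mean, sd)


def _subsample_support(
    mats: dict[str, AnchorOffsetMatrix], rng: np.random.Generator, frac: float
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Pick ``frac`` of the nonzero cells (without replacement) across chromosomes."""
    cells = []
    for chrom, mat in mats.items():
        r, c = np.nonzero(mat.values)
        cells.append((chrom, r, c))
    total = sum(r.size for _, r, _ in cells)
    n_take = int(math.floor(frac * total))
    chosen = rng.choice(total, size=n_take, replace=False)
    mask = np.zeros(total, dtype=bool)
    mask[chosen] = True
    out, pos = [], 0
    for chrom, r, c in cells:
        sel = mask[pos : pos + r.size]
        out.append((chrom, r[sel], c[sel]))
        pos += r.size
    return out


def tune_smoothing(
    mats_a: dict[str, AnchorOffsetMatrix],
    mats_b: dict[str, AnchorOffsetMatrix],
    seed: int,
    n_reps: int = 10,
    frac: float = 0.25,
    min_increase: float = 0.01,
    max_d: int = 20,
) -> tuple[int, list[tuple[int, float]]]:
    """Choose the smoothing half-width d by repeated 25% subsampling.

    For each candidate d = 0, 1, 2, ...: draw ``n_reps`` independent
    subsamples of 25% of sample A's nonzero matrix cells (zeroing the
    rest), restrict sample B to the same positions, score the pair at
    smoothing d, and average.  Stop at the first d whose successor improves
    the average by less than ``min_increase`` (relative), and return d with
    the (d, mean score) trajectory.  Deterministic given ``seed``.

    Tuning is intended to be run once per study on a dissimilar pair
    (ideally non-replicates) and the returned d reused for all pairs.
    """
    rng = np.random.default_rng(seed)
    trajectory: list[tuple[int, float]] = []

    def mean_score(d: int) -> float:
        scores = []
        for _ in range(n_reps):
            picked = _subsample_support(mats_a, rng, frac)
            sub_a, sub_b = {}, {}
            for chrom, rows, cols in picked:
                va = np.zeros_like(mats_a[chrom].values)
                vb = np.zeros_like(mats_b[chrom].values)
                va[rows, cols] = mats_a[chrom].values[rows, cols]
                vb[rows, cols] = mats_b[chrom].values[rows, cols]
                sub_a[chrom] = replace(mats_a[chrom], values=va)
                sub_b[chrom] = replace(mats_b[chrom], values=vb)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                scores.append(genome_score(sub_a, sub_b, d).mean)
        return float(np.mean(scores))

    current = mean_score(0)
    if math.isnan(current):
        raise ValueError(
            "subsampled scores are undefined at d=0; choose a different sample pair"
        )
    trajectory.append((0, current))
    for d in range(0, max_d):
        nxt = mean_score(d + 1)
        trajectory.append((d + 1, nxt))
        if nxt < (1.0 + min_increase) * current:
            return d, trajectory
        current = nxt
    warnings.warn(f"tuning did not plateau by d={max_d}; returning d={max_d}", RuntimeWarning)
    return max_d, trajectory


def naive_pearson(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """Pearson correlation of flattened upper triangles of two square contact matrices.

    The baseline comparator: no normalization, smoothing or stratification.
    """
    mat_a = np.asarray(mat_a, dtype=float)
    mat_b = np.asarray(mat_b, dtype=float)
    if mat_a.shape != mat_b.shape or mat_a.shape[0] != mat_a.shape[1]:
        raise ValueError("matrices must be square and share a bin grid")
    iu = np.triu_indices(mat_a.shape[0], k=0)
    a, b = mat_a[iu], mat_b[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
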