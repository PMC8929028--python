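"""Synthetic HiChIP/PLAC-Seq study generator.

Emulates everything the pipeline consumes — per-bin features, ChIP peak
intervals, and AND/XOR bin-pair contact tables for several samples — with
controllable anchor overlap between conditions, sequencing depth and
replicate structure, so every stage runs without external data.

Generative model
----------------
Each condition owns an anchor set (a shared core across conditions sized
to hit a target Jaccard overlap, plus private anchors) and a sparse set of
"true loops" among its candidate anchor-offset cells.  A fraction
``loop_share`` of every condition's loops comes from a study-wide pool
anchored on the shared core — cell types share most of their promoter
interactome — and the rest is condition-private.  For every candidate
bin pair the log mean is

    log mu = b1*FL + b2*GC + b3*MS + b4*IP            (bias covariates)
           + shared background field                  (compartment/TAD-like)
           + loop amplitude (shared pool + condition-private)
           + and_boost for AND pairs                  (double enrichment)
           - decay_exponent * log(offset)             (distance decay)
           + replicate log-normal noise,

globally rescaled so the expected total long-range count equals ``depth``;
counts are Poisson draws with zero outcomes dropped (i.e. zero-truncated
support, matching what the normalization models).  Replicates of one
condition share anchors, loops and the genome-side covariates and differ
only in ChIP-efficiency jitter, noise and counting; conditions differ in
anchors and loops.

Real-data features deliberately not modelled: restriction-fragment
structure, ligation artifacts, trans contacts, copy-number variation.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io_formats import (
    AnchorSet,
    SampleSpec,
    StudyConfig,
    write_bin_features,
    write_bin_pairs,
)
from .resampling import Tables, subseed

__all__ = [
    "SimConfig",
    "SyntheticSample",
    "SyntheticStudy",
    "simulate_condition_anchors",
    "simulate_bin_features",
    "simulate_sample",
    "simulate_study",
    "simulate_ztp_pairs",
    "simulate_unclassified_pairs",
    "write_study",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults are a desk-scale study: 2 chromosomes of 2,000 bins at 10 Kb
    (20 Mb each), two conditions with two replicates, 6% of bins carrying a
    ChIP peak, anchor Jaccard 0.54 between conditions (promoter-mark-like
    sharing), 2x10^5 expected long-range contacts per sample, distance
    decay exponent 1 and moderate replicate noise.
    """

    n_chroms: int = 2
    n_bins: int = 2000
    resolution: int = 10_000
    binning_distance: int = 1_000_000
    n_conditions: int = 2
    n_replicates: int = 2
    anchor_density: float = 0.06
    anchor_jaccard: float = 0.54
    depth: float = 2e5
    decay_exponent: float = 1.0
    beta_true: tuple[float, float, float, float, float] = (1.0, 0.3, -0.2, 0.1, 0.5)
    noise_sd: float = 0.3
    loop_density: float = 0.02
    loop_strength: float = 1.5
    loop_share: float = 0.5
    background_sd: float = 0.5
    and_boost: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.anchor_jaccard <= 1.0:
            raise ValueError("anchor_jaccard must be in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if len(self.beta_true) != 5:
            raise ValueError("beta_true must have 5 entries (intercept + 4 slopes)")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(f"sim{i + 1}" for i in range(self.n_chroms))

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.resolution

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(string.ascii_uppercase[: self.n_conditions])

    @property
    def n_strata(self) -> int:
        return self.binning_distance // self.resolution


@dataclass
class SyntheticSample:
    id: str
    condition: str
    tables: Tables  # chrom -> pair class -> bin-pair table
    features: pd.DataFrame


@dataclass
class SyntheticStudy:
    config: SimConfig
    condition_anchors: dict[str, AnchorSet]
    union_anchors: AnchorSet
    samples: dict[str, SyntheticSample]

    @property
    def labels(self) -> dict[str, str]:
        return {sid: s.condition for sid, s in self.samples.items()}

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            resolution=self.config.resolution,
            binning_distance=self.config.binning_distance,
            chromosomes=self.config.chromosomes,
            seed=self.config.seed,
        )


def simulate_condition_anchors(cfg: SimConfig) -> dict[str, AnchorSet]:
    """Per-condition anchor sets hitting the target pairwise Jaccard overlap.

    Every condition carries ``s`` anchors per chromosome: a core of
    ``c = round(2 s J / (1 + J))`` bins shared by all conditions plus
    ``s - c`` private bins, giving pairwise Jaccard ``c / (2s - c)``.
    """
    s = int(round(cfg.anchor_density * cfg.n_bins))
    if s < 2:
        raise ValueError("anchor_density too low: fewer than 2 anchors per chromosome")
    core = int(round(2 * s * cfg.anchor_jaccard / (1 + cfg.anchor_jaccard)))
    core = min(core, s)
    private = s - core
    needed = core + cfg.n_conditions * private
    if needed > cfg.n_bins:
        raise ValueError(
            f"infeasible anchor target: need {needed} distinct bins > {cfg.n_bins}; "
            "raise n_bins, lower anchor_density, or raise anchor_jaccard"
        )
    realized = core / (2 * s - core) if s else float("nan")
    if abs(realized - cfg.anchor_jaccard) > 0.05:
        raise ValueError(
            f"cannot realize Jaccard {cfg.anchor_jaccard} within 0.05 "
            f"(closest achievable {realized:.3f}); increase n_bins or anchor_density"
        )
    out: dict[str, dict[str, np.ndarray]] = {c: {} for c in cfg.conditions}
    for chrom in cfg.chromosomes:
        rng = np.random.default_rng(subseed(cfg.seed, "anchors", chrom))
        pool = rng.permutation(cfg.n_bins) * cfg.resolution
        shared = pool[:core]
        cursor = core
        for cond in cfg.conditions:
            mine = pool[cursor : cursor + private]
            cursor += private
            out[cond][chrom] = np.sort(np.concatenate([shared, mine]))
    return {c: AnchorSet(cfg.resolution, bins) for c, bins in out.items()}


def simulate_bin_features(cfg: SimConfig) -> pd.DataFrame:
    """Genome-side per-bin features (effective length, GC, mappability) plus
    a baseline short-read intensity shared by all samples."""
    rng = np.random.default_rng(subseed(cfg.seed, "features"))
    frames = []
    for chrom in cfg.chromosomes:
        starts = np.arange(cfg.n_bins, dtype=np.int64) * cfg.resolution
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": starts,
                    "effective_length": rng.uniform(0.5, 1.0, cfg.n_bins)
                    * cfg.resolution,
                    "gc": rng.uniform(0.30, 0.65, cfg.n_bins),
                    "mappability": rng.uniform(0.70, 1.00, cfg.n_bins),
                    "short_base": rng.gamma(5.0, 20.0, cfg.n_bins),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _candidate_pairs(
    anchors: np.ndarray, cfg: SimConfig
) -> pd.DataFrame:
    """All deduplicated (bin1 < bin2) pairs with one end an anchor and
    separation within the binning distance."""
    offsets = np.concatenate(
        [np.arange(-cfg.n_strata, 0), np.arange(1, cfg.n_strata + 1)]
    )
    a = np.repeat(anchors, offsets.size)
    other = a + np.tile(offsets, anchors.size) * cfg.resolution
    ok = (other >= 0) & (other < cfg.chrom_length)
    a, other = a[ok], other[ok]
    bin1 = np.minimum(a, other)
    bin2 = np.maximum(a, other)
    df = pd.DataFrame({"bin1": bin1, "bin2": bin2}).drop_duplicates(ignore_index=True)
    return df.sort_values(["bin1", "bin2"], ignore_index=True)


def _intersect_all(arrays: list[np.ndarray]) -> np.ndarray:
    out = arrays[0]
    for arr in arrays[1:]:
        out = np.intersect1d(out, arr, assume_unique=True)
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_sample(
    cfg: SimConfig, condition: str, replicate: int
) -> SyntheticSample:
    """Generate one replicate's AND/XOR tables and per-bin feature table."""
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    all_anchors = simulate_condition_anchors(cfg)
    anchors = all_anchors[condition]
    core_bins = {
        chrom: _intersect_all([a.chrom_anchors(chrom) for a in all_anchors.values()])
        for chrom in cfg.chromosomes
    }
    features = simulate_bin_features(cfg)
    sid = f"{condition}{replicate}"
    rng_rep = np.random.default_rng(subseed(cfg.seed, "replicate", condition, replicate))
    _, b_fl, b_gc, b_ms, b_ip = cfg.beta_true

    # replicate-specific ChIP efficiency: anchor bins enriched, log-normal jitter
    feat = features.copy()
    boost = np.ones(len(feat))
    for chrom, grp in feat.groupby("chrom", sort=False):
        is_anchor = anchors.contains(chrom, grp["bin_start"].to_numpy())
        boost[grp.index.to_numpy()[is_anchor]] = 5.0
    feat["short_count"] = (
        feat["short_base"].to_numpy()
        * boost
        * rng_rep.lognormal(0.0, 0.2, len(feat))
    )

    per_chrom_mu: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}
    for chrom in cfg.chromosomes:
        ca = anchors.chrom_anchors(chrom)
        pairs = _candidate_pairs(ca, cfg)
        fc = feat[feat["chrom"] == chrom].set_index("bin_start")
        i1 = pairs["bin1"].to_numpy()
        i2 = pairs["bin2"].to_numpy()

        def logprod(col: str) -> np.ndarray:
            x = fc[col]
            return np.log(x.loc[i1].to_numpy() * x.loc[i2].to_numpy())

        cov = pd.DataFrame(
            {
                "fl": _zscore(logprod("effective_length")),
                "gc": _zscore(logprod("gc")),
                "ms": _zscore(logprod("mappability")),
                "ip": _zscore(logprod("short_count")),
            }
        )
        in1 = anchors.contains(chrom, i1)
        in2 = anchors.contains(chrom, i2)
        is_and = in1 & in2
        k = (i2 - i1) // cfg.resolution

        # loop field shared by replicates: a study-wide pool on the core
        # anchors plus a condition-private remainder
        n_loops = int(round(cfg.loop_density * len(pairs)))
        n_shared = int(round(cfg.loop_share * n_loops))
        loops = np.zeros(len(pairs))
        core_pairs = _candidate_pairs(core_bins[chrom], cfg)
        if n_shared > 0 and len(core_pairs) > 0:
            rng_shared = np.random.default_rng(subseed(cfg.seed, "loops", "shared", chrom))
            n_shared = min(n_shared, len(core_pairs))
            idx = rng_shared.choice(len(core_pairs), size=n_shared, replace=False)
            amps = rng_shared.gamma(2.0, cfg.loop_strength / 2.0, n_shared)
            shared = core_pairs.iloc[idx].assign(amp=amps)
            merged = pairs.merge(shared, on=["bin1", "bin2"], how="left")
            loops += merged["amp"].fillna(0.0).to_numpy()
        rng_cond = np.random.default_rng(subseed(cfg.seed, "loops", condition, chrom))
        n_private = n_loops - n_shared
        if n_private > 0:
            loop_idx = rng_cond.choice(len(pairs), size=n_private, replace=False)
            loops[loop_idx] += rng_cond.gamma(2.0, cfg.loop_strength / 2.0, n_private)

        # contact-structure field shared by all samples (compartment/TAD-like
        # variation beyond the bias covariates), keyed by (bin1, offset)
        rng_bg = np.random.default_rng(subseed(cfg.seed, "background", chrom))
        field = rng_bg.normal(0.0, cfg.background_sd, size=(cfg.n_bins, cfg.n_strata))
        background = field[i1 // cfg.resolution, k - 1]

        eta = (
            background
            + b_fl * cov["fl"].to_numpy()
            + b_gc * cov["gc"].to_numpy()
            + b_ms * cov["ms"].to_numpy()
            + b_ip * cov["ip"].to_numpy()
            + loops
            + cfg.and_boost * is_and
            - cfg.decay_exponent * np.log(k)
            + rng_rep.normal(0.0, cfg.noise_sd, len(pairs))
        )
        table = pd.DataFrame(
            {
                "chrom": chrom,
                "bin1": i1,
                "bin2": i2,
                "count": 0,
                "fl": cov["fl"],
                "gc": cov["gc"],
                "ms": cov["ms"],
                "ip": cov["ip"],
                "pair_class": np.where(is_and, "AND", "XOR"),
            }
        )
        per_chrom_mu[chrom] = (table, np.exp(eta))

    total_mu = sum(mu.sum() for _, mu in per_chrom_mu.values())
    scale = cfg.depth / total_mu
    tables: Tables = {}
    for chrom, (table, mu) in per_chrom_mu.items():
        counts = rng_rep.poisson(scale * mu)
        table = table.assign(count=counts)
        table = table[table["count"] > 0].reset_index(drop=True)
        tables[chrom] = {
            cls: grp.reset_index(drop=True)
            for cls, grp in table.groupby("pair_class", sort=True)
        }
        for cls in ("AND", "XOR"):
            tables[chrom].setdefault(
                cls,
                pd.DataFrame(
                    columns=["chrom", "bin1", "bin2", "count", "fl", "gc", "ms", "ip", "pair_class"]
                ),
            )
    return SyntheticSample(
        id=sid,
        condition=condition,
        tables=tables,
        features=feat[
            ["chrom", "bin_start", "effective_length", "gc", "mappability", "short_count"]
        ].copy(),
    )


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate the full multi-condition, multi-replicate study."""
    condition_anchors = simulate_condition_anchors(cfg)
    union_bins: dict[str, list[np.ndarray]] = {}
    for aset in condition_anchors.values():
        for chrom, arr in aset.bins.items():
            union_bins.setdefault(chrom, []).append(arr)
    union = AnchorSet(
        cfg.resolution, {c: np.unique(np.concatenate(v)) for c, v in union_bins.items()}
    )
    samples = {}
    for cond in cfg.conditions:
        for rep in range(1, cfg.n_replicates + 1):
            s = simulate_sample(cfg, cond, rep)
            samples[s.id] = s
    return SyntheticStudy(cfg, condition_anchors, union, samples)


def simulate_ztp_pairs(
    beta: tuple[float, ...], n: int, seed: int, resolution: int = 10_000
) -> pd.DataFrame:
    """Pure zero-truncated Poisson bin-pair table for regression testing.

    Covariates are iid Normal(0, 0.5); counts are exact ZTP draws (inverse
    CDF) from ``mu = exp(beta . x)``.  This is the parameter-recovery
    oracle for the normalization fit: no decay, loops or replicate noise.
    """
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(0.0, 0.5, size=(n, 4))])
    mu = np.exp(X @ beta)
    p0 = np.exp(-mu)
    u = rng.uniform(size=n)
    y = stats.poisson.ppf(p0 + u * (1.0 - p0), mu).astype(np.int64)
    y = np.maximum(y, 1)
    bin1 = np.arange(n, dtype=np.int64) * resolution
    return pd.DataFrame(
        {
            "chrom": "sim1",
            "bin1": bin1,
            "bin2": bin1 + 2 * resolution,
            "count": y,
            "fl": X[:, 1],
            "gc": X[:, 2],
            "ms": X[:, 3],
            "ip": X[:, 4],
            "pair_class": "AND",
        }
    )


def simulate_unclassified_pairs(
    cfg: SimConfig, chrom: str, n: int, seed: int
) -> pd.DataFrame:
    """Random long-range bin pairs over all bins (AND, XOR and NOT mixed),
    for exercising classification."""
    rng = np.random.default_rng(seed)
    b1 = rng.integers(0, cfg.n_bins - 1, n) * cfg.resolution
    gap = rng.integers(1, cfg.n_strata + 1, n) * cfg.resolution
    b2 = np.minimum(b1 + gap, (cfg.n_bins - 1) * cfg.resolution)
    keep = b2 > b1
    return pd.DataFrame(
        {
            "chrom": chrom,
            "bin1": b1[keep],
            "bin2": b2[keep],
            "count": rng.integers(1, 10, int(keep.sum())),
            "fl": 0.0,
            "gc": 0.0,
            "ms": 0.0,
            "ip": 0.0,
        }
    )


def _peaks_from_anchors(anchors: AnchorSet) -> pd.DataFrame:
    """Merge runs of consecutive anchor bins into peak intervals.

    Multi-bin runs become single peaks spanning bin boundaries, so binning
    the peaks back to resolution recovers the anchor set exactly.
    """
    res = anchors.resolution
    rows = []
    for chrom in sorted(anchors.bins):
        arr = anchors.bins[chrom]
        if arr.size == 0:
            continue
        breaks = np.nonzero(np.diff(arr) != res)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [arr.size - 1]])
        for s, e in zip(starts, ends):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(arr[s] + res // 4),
                    "end": int(arr[e] + res - res // 4),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Emit the study as on-disk artifacts plus a ``study.yaml`` config.

    Layout: ``<out>/<sample>/<chrom>.{and,xor}.tsv`` and
    ``<out>/<sample>/features.tsv`` per sample; ``<out>/peaks/<cond>.bed``
    per condition.  Byte-identical across runs with the same seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for cond, aset in study.condition_anchors.items():
        _peaks_from_anchors(aset).to_csv(
            peaks_dir / f"{cond}.bed", sep="\t", header=False, index=False
        )
    sample_specs = []
    for sid, sample in study.samples.items():
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        for chrom, by_class in sample.tables.items():
            for cls, df in by_class.items():
                write_bin_pairs(df, sdir / f"{chrom}.{cls.lower()}.tsv")
        write_bin_features(sample.features, sdir / "features.tsv")
        # paths relative to the study directory keep the emitted study
        # relocatable and byte-identical across runs
        sample_specs.append(
            {
                "id": sid,
                "condition": sample.condition,
                "tables": sid,
                "peaks": f"peaks/{sample.condition}.bed",
            }
        )
    config = {
        "resolution": study.config.resolution,
        "binning_distance": study.config.binning_distance,
        "chromosomes": list(study.config.chromosomes),
        "smoothing_d": "tune",
        "seed": study.config.seed,
        "samples": sample_specs,
    }
    with open(outdir / "study.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return outdir / "study.yaml"
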