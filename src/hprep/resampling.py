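"""Depth manipulation: multinomial downsampling and pseudo-replicates.

Downsampling redraws a contact table's counts from
``Multinomial(floor(n * factor), v / n)`` where ``v`` is the vector of
bin-pair counts and ``n`` its total, separately per (chromosome, pair
class) file; bin pairs drawn to zero are removed.  Pseudo-replicates pool
two same-condition samples and split each pooled bin-pair count
``Binomial(c, 0.5)`` between two artificial samples — the empirical upper
bound of attainable similarity.

Randomness is reproducible: every file draws from a sub-seed derived by
stable hashing of (master seed, sample id, chromosome, pair class), so
adding a sample never perturbs another sample's draws.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

__all__ = ["subseed", "downsample", "downsample_tables", "make_pseudo_replicates"]

Tables = dict[str, dict[str, pd.DataFrame]]  # chrom -> pair class -> table


def subseed(master: int, *parts: object) -> int:
    """Stable sub-seed < 2**31 from a master seed and context labels."""
    key = ":".join([str(int(master))] + [str(p) for p in parts]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def downsample(pairs: pd.DataFrame, factor: float, seed: int) -> pd.DataFrame:
    """Multinomial downsampling of one contact table to ``floor(n * factor)`` reads.

    Covariates ride along unchanged; rows downsampled to zero are dropped.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"downsampling factor must be in (0, 1], got {factor}")
    counts = pairs["count"].to_numpy(dtype=np.int64)
    n = int(counts.sum())
    if n < 1:
        raise ValueError("cannot downsample an empty contact table")
    rng = np.random.default_rng(seed)
    new_counts = rng.multinomial(int(np.floor(n * factor)), counts / n)
    out = pairs.copy()
    out["count"] = new_counts
    return out[out["count"] > 0].reset_index(drop=True)


def downsample_tables(
    tables: Tables, factor: float, seed: int, sample_id: str = ""
) -> Tables:
    """Downsample every (chromosome, class) file of a sample independently."""
    out: Tables = {}
    for chrom, by_class in tables.items():
        out[chrom] = {}
        for cls, df in by_class.items():
            if df.empty:
                out[chrom][cls] = df.copy()
                continue
            out[chrom][cls] = downsample(
                df, factor, subseed(seed, sample_id, chrom, cls)
            )
    return out


def _pool(df_a: pd.DataFrame, df_b: pd.DataFrame) -> pd.DataFrame:
    keys = ["chrom", "bin1", "bin2"]
    covs = ["fl", "gc", "ms", "ip"]
    merged = df_a.merge(df_b, on=keys, how="outer", suffixes=("_a", "_b"))
    pooled = merged[keys].copy()
    ca = merged["count_a"].fillna(0).to_numpy(dtype=np.int64)
    cb = merged["count_b"].fillna(0).to_numpy(dtype=np.int64)
    pooled["count"] = ca + cb
    for c in covs:
        # covariates are bin properties: average where both samples report them
        pooled[c] = merged[[f"{c}_a", f"{c}_b"]].mean(axis=1).to_numpy()
    return pooled.sort_values(keys, kind="mergesort").reset_index(drop=True)


def make_pseudo_replicates(
    tables_a: Tables, tables_b: Tables, seed: int
) -> tuple[Tables, Tables]:
    """Pool two same-condition samples and split counts Binomial(c, 0.5).

    Per pooled bin pair the two pseudo samples' counts sum exactly to the
    pooled count; zero outcomes are dropped from each pseudo table.  The
    pseudo tables are valid bin-pair tables and re-enter the pipeline at
    the normalization step.
    """
    pseudo_a: Tables = {}
    pseudo_b: Tables = {}
    for chrom in sorted(set(tables_a) | set(tables_b)):
        pseudo_a[chrom], pseudo_b[chrom] = {}, {}
        classes = set(tables_a.get(chrom, {})) | set(tables_b.get(chrom, {}))
        for cls in sorted(classes):
            empty = pd.DataFrame(
                columns=["chrom", "bin1", "bin2", "count", "fl", "gc", "ms", "ip"]
            )
            df_a = tables_a.get(chrom, {}).get(cls, empty)
            df_b = tables_b.get(chrom, {}).get(cls, empty)
            pooled = _pool(df_a, df_b)
            rng = np.random.default_rng(subseed(seed, "pseudo", chrom, cls))
            half = rng.binomial(pooled["count"].to_numpy(dtype=np.int64), 0.5)
            for which, counts in (("a", half), ("b", pooled["count"].to_numpy() - half)):
                part = pooled.copy()
                part["count"] = counts
                part["pair_class"] = cls
                part = part[part["count"] > 0].reset_index(drop=True)
                (pseudo_a if which == "a" else pseudo_b)[chrom][cls] = part
    return pseudo_a, pseudo_b
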