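"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately naive (explicit loops, raw-moment
formulas) and shares no code with the library paths it validates.
"""

from __future__ import annotations

import math

import numpy as np


def smooth_rows_loop(values: np.ndarray, d: int) -> np.ndarray:
    """Row-wise sliding mean, zero-padded, divisor 2d+1, by explicit loops."""
    n, m = values.shape
    out = np.zeros_like(values, dtype=float)
    for i in range(n):
        for j in range(m):
            total = 0.0
            for k in range(j - d, j + d + 1):
                if 0 <= k < m:
                    total += values[i, k]
            out[i, j] = total / (2 * d + 1)
    return out


def monolithic_score(values_a: np.ndarray, values_b: np.ndarray, d: int) -> float:
    """Stratified weighted correlation computed in one pass from raw grids.

    ``values_*`` are N x m arrays whose columns are the signed offsets
    (-K..-1, +1..+K).  Smoothing, joint-zero removal, per-stratum
    population-moment Pearson correlations and N_k*sd*sd weights are all
    evaluated with scalar arithmetic.
    """
    n, m = values_a.shape
    K = m // 2
    A = smooth_rows_loop(values_a, d)
    B = smooth_rows_loop(values_b, d)
    weights, corrs = [], []
    for k in range(1, K + 1):
        a = np.concatenate([A[:, K - k], A[:, K + k - 1]])
        b = np.concatenate([B[:, K - k], B[:, K + k - 1]])
        keep = (a != 0) | (b != 0)
        a, b = a[keep], b[keep]
        nk = a.size
        if nk < 2:
            continue
        var_a = float(np.mean(a * a) - np.mean(a) ** 2)
        var_b = float(np.mean(b * b) - np.mean(b) ** 2)
        if var_a <= 0 or var_b <= 0:
            continue
        sd_a, sd_b = math.sqrt(var_a), math.sqrt(var_b)
        r = (float(np.mean(a * b)) - float(np.mean(a)) * float(np.mean(b))) / (sd_a * sd_b)
        weights.append(nk * sd_a * sd_b)
        corrs.append(r)
    if not weights:
        return float("nan")
    w = np.array(weights) / sum(weights)
    return float(np.sum(w * np.array(corrs)))


def silhouette_loop(sim: np.ndarray, labels: list[str]) -> float:
    """Mean similarity-silhouette by explicit enumeration."""
    n = len(labels)
    values = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            values.append(0.0)
            continue
        a = np.mean([sim[i, j] for j in same])
        rival = -np.inf
        for cl in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == cl]
            rival = max(rival, np.mean([sim[i, j] for j in members]))
        values.append((a - rival) / max(a, rival))
    return float(np.mean(values))
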