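"""Zero-truncated Poisson normalization of bin-pair contact counts.

Observed non-zero contact counts are modelled as zero-truncated Poisson
(ZTP) with a log-linear mean in four bias covariates,

    log(mu) = b0 + b1*FL + b2*GC + b3*MS + b4*IP,

where FL, GC, MS and IP are pair-level log-products of per-bin effective
fragment length, GC content, mappability and ChIP enrichment (short-range
read abundance).  Separate models are fitted per chromosome for the AND
set (both ends anchor bins) and the XOR set (exactly one end an anchor
bin), because double ChIP enrichment inflates AND counts.  The normalized
contact value is ``log2(1 + observed / fitted)`` where the fitted value is
the truncated mean ``E[Y | Y > 0] = mu / (1 - exp(-mu))``.

Fitting is Newton-Raphson on the ZTP log-likelihood with analytic gradient
and Hessian (the log link is canonical for this family, so observed and
expected information coincide), initialised from an ordinary Poisson GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "COVARIATES",
    "MIN_RECORDS",
    "RegressionFit",
    "classify_pairs",
    "split_short_long",
    "short_counts_per_bin",
    "ztp_loglik",
    "truncated_mean",
    "fit_ztp",
    "predict_fitted",
    "normalize_pairs",
    "normalize_chromosome",
    "normalize_sample",
    "fit_summary_table",
]

COVARIATES = ["fl", "gc", "ms", "ip"]
N_PARAMS = 1 + len(COVARIATES)

#: below this many bin pairs the ZTP MLE is unreliable and the fit is refused
MIN_RECORDS = 50

_ETA_MAX = 700.0  # exp() overflow guard


@dataclass
class RegressionFit:
    """A fitted per-chromosome ZTP regression for one pair class."""

    pair_class: str
    chrom: str
    beta: np.ndarray  # (b0, b_FL, b_GC, b_MS, b_IP)
    converged: bool
    n_obs: int
    loglik: float
    n_iter: int
    cov_beta: np.ndarray  # inverse Fisher information at the optimum

    @property
    def aic(self) -> float:
        return 2 * N_PARAMS - 2 * self.loglik

    @property
    def bic(self) -> float:
        return N_PARAMS * np.log(self.n_obs) - 2 * self.loglik

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def classify_pairs(pairs: pd.DataFrame, anchors) -> dict[str, pd.DataFrame]:
    """Partition bin pairs into AND / XOR / NOT by anchor-bin membership of their ends.

    A pair is AND, XOR or NOT according to whether 2, 1 or 0 of its ends
    fall in anchor bins.  NOT pairs are returned for completeness but are
    excluded from downstream analysis.
    """
    n_anchor_ends = np.zeros(len(pairs), dtype=np.int64)
    for chrom, grp in pairs.groupby("chrom", sort=False):
        in1 = anchors.contains(chrom, grp["bin1"].to_numpy())
        in2 = anchors.contains(chrom, grp["bin2"].to_numpy())
        n_anchor_ends[grp.index.to_numpy()] = in1.astype(int) + in2.astype(int)
    labels = np.array(["NOT", "XOR", "AND"])[n_anchor_ends]
    out = {}
    for cls in ("AND", "XOR", "NOT"):
        sub = pairs[labels == cls].copy()
        sub["pair_class"] = cls
        out[cls] = sub.reset_index(drop=True)
    return out


def split_short_long(
    read_pairs: pd.DataFrame, threshold: int = 1000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split intra-chromosomal read pairs into short-range (<= 1 Kb) and long-range (> 1 Kb).

    ``read_pairs`` needs columns ``pos1``/``pos2`` (bp) or a precomputed
    ``separation``.  Short-range reads measure ChIP efficiency; long-range
    reads carry the interaction signal.
    """
    if "separation" in read_pairs.columns:
        sep = read_pairs["separation"].to_numpy()
    else:
        sep = np.abs(read_pairs["pos2"].to_numpy() - read_pairs["pos1"].to_numpy())
    if (sep < 0).any():
        raise ValueError("negative read-pair separation")
    short = read_pairs[sep <= threshold].reset_index(drop=True)
    long = read_pairs[sep > threshold].reset_index(drop=True)
    return short, long


def short_counts_per_bin(short: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Aggregate short-range read ends per bin (the IP covariate's raw material).

    Each read pair contributes both of its end bins, i.e. counts are read
    ends, not pairs.
    """
    ends = pd.concat(
        [
            short[["chrom", "pos1"]].rename(columns={"pos1": "pos"}),
            short[["chrom", "pos2"]].rename(columns={"pos2": "pos"}),
        ],
        ignore_index=True,
    )
    ends["bin_start"] = (ends["pos"] // resolution) * resolution
    out = (
        ends.groupby(["chrom", "bin_start"]).size().rename("short_count").reset_index()
    )
    return out


def _design(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack(
        [np.ones(len(pairs))] + [pairs[c].to_numpy(dtype=float) for c in COVARIATES]
    )
    y = pairs["count"].to_numpy(dtype=float)
    return X, y


def ztp_loglik(beta: np.ndarray, pairs: pd.DataFrame) -> float:
    """Zero-truncated Poisson log-likelihood of ``pairs`` under coefficients ``beta``.

    Sum over pairs of ``y*log(mu) - mu - log(y!) - log(1 - exp(-mu))`` with
    ``mu = exp(beta . x)``.
    """
    X, y = _design(pairs)
    if (y < 1).any():
        raise ValueError("ZTP likelihood requires counts >= 1")
    return _loglik(np.asarray(beta, dtype=float), X, y)


def _loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    if np.any(eta > _ETA_MAX):
        raise OverflowError("fitted mean exceeds exp(700); divergent fit")
    mu = np.exp(eta)
    return float(np.sum(y * eta - mu - gammaln(y + 1) - np.log(-np.expm1(-mu))))


def truncated_mean(mu: np.ndarray | float) -> np.ndarray | float:
    """``E[Y | Y > 0] = mu / (1 - exp(-mu))`` for Poisson mean ``mu``."""
    return mu / -np.expm1(-mu)


def _poisson_init(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return np.asarray(res.params, dtype=float)


def fit_ztp(
    pairs: pd.DataFrame,
    pair_class: str = "AND",
    chrom: str = "",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RegressionFit:
    """Maximum-likelihood ZTP regression fit.

    Newton-Raphson with analytic gradient ``X'(y - E[Y|Y>0])`` and Fisher
    information ``X' diag(Var(Y|Y>0)) X``, initialised from an ordinary
    Poisson GLM; step-halving guards the line search.  Converged means the
    gradient infinity-norm fell below ``tol``.

    Raises
    ------
    ValueError
        Fewer than ``MIN_RECORDS`` pairs, or a rank-deficient design.
    RuntimeError
        No convergence within ``max_iter`` iterations.
    """
    if len(pairs) < MIN_RECORDS:
        raise ValueError(
            f"refusing to fit {pair_class}/{chrom or '?'}: {len(pairs)} bin pairs "
            f"< required minimum {MIN_RECORDS}"
        )
    X_full, y = _design(pairs)
    if (y < 1).any():
        raise ValueError("ZTP fit requires counts >= 1 (drop zero rows at read time)")
    # all-zero covariate columns carry no information: pin their slope at 0
    active = [0] + [j for j in range(1, N_PARAMS) if np.any(X_full[:, j] != 0)]
    X = X_full[:, active]
    rank = np.linalg.matrix_rank(X)
    if rank < len(active):
        names = [COVARIATES[j - 1] for j in active[1:]]
        corr = np.atleast_2d(np.corrcoef(X[:, 1:], rowvar=False))
        culprits = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 0.999
        ]
        detail = f" (collinear: {', '.join(culprits)})" if culprits else ""
        raise ValueError(f"design matrix rank {rank} < {len(active)}{detail}")

    beta = _poisson_init(X, y)
    ll = _loglik(beta, X, y)
    converged = False
    n_iter = 0
    fisher = np.eye(N_PARAMS)
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        if np.any(eta > _ETA_MAX):
            raise OverflowError("fitted mean exceeds exp(700); divergent fit")
        mu = np.exp(eta)
        expect = truncated_mean(mu)
        grad = X.T @ (y - expect)
        var = expect * (1.0 + mu - expect)  # ZTP variance; canonical-link information
        fisher = X.T @ (X * var[:, None])
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        step = np.linalg.solve(fisher, grad)
        # step-halving line search; tolerance scaled to |loglik| for float noise
        ll_tol = 1e-10 * (1.0 + abs(ll))
        for _ in range(30):
            candidate = beta + step
            try:
                ll_new = _loglik(candidate, X, y)
            except OverflowError:
                ll_new = -np.inf
            if ll_new >= ll - ll_tol:
                break
            step = step / 2.0
        else:
            raise RuntimeError(
                f"ZTP line search failed for {pair_class}/{chrom}; last beta {beta}"
            )
        beta, ll = candidate, ll_new
    if not converged:
        raise RuntimeError(
            f"ZTP fit did not converge in {max_iter} iterations for "
            f"{pair_class}/{chrom}; last beta {beta}"
        )
    if np.max(np.exp(X @ beta)) < 1e-8:
        warnings.warn(
            f"ZTP fit for {pair_class}/{chrom} is at the mu -> 0 boundary "
            "(mean count ~ 1); coefficients are weakly identified",
            RuntimeWarning,
        )
    beta_full = np.zeros(N_PARAMS)
    beta_full[active] = beta
    cov_full = np.zeros((N_PARAMS, N_PARAMS))
    cov_full[np.ix_(active, active)] = np.linalg.inv(fisher)
    return RegressionFit(
        pair_class=pair_class,
        chrom=chrom,
        beta=beta_full,
        converged=converged,
        n_obs=len(pairs),
        loglik=ll,
        n_iter=n_iter,
        cov_beta=cov_full,
    )


def predict_fitted(fit: RegressionFit, pairs: pd.DataFrame) -> np.ndarray:
    """Fitted values ``E[Y | Y > 0] = mu / (1 - exp(-mu))`` with ``mu = exp(beta . x)``."""
    if not fit.converged:
        raise ValueError("cannot predict from an unconverged fit")
    X, _ = _design(pairs)
    mu = np.exp(X @ fit.beta)
    return np.asarray(truncated_mean(mu))


def normalize_pairs(pairs: pd.DataFrame, fitted: np.ndarray) -> pd.DataFrame:
    """Attach ``normalized = log2(1 + observed / fitted)`` to a pair table."""
    fitted = np.asarray(fitted, dtype=float)
    if (fitted <= 0).any():
        raise ValueError("fitted values must be strictly positive")
    out = pairs.copy()
    out["fitted"] = fitted
    out["normalized"] = np.log2(1.0 + out["count"].to_numpy() / fitted)
    return out


def normalize_chromosome(
    pairs: pd.DataFrame, pair_class: str, chrom: str
) -> tuple[RegressionFit, pd.DataFrame]:
    fit = fit_ztp(pairs, pair_class=pair_class, chrom=chrom)
    return fit, normalize_pairs(pairs, predict_fitted(fit, pairs))


def normalize_sample(
    tables: dict[str, dict[str, pd.DataFrame]],
) -> tuple[list[RegressionFit], pd.DataFrame]:
    """Normalize one sample: per-chromosome AND and XOR fits, combined output.

    ``tables`` maps chromosome -> pair class -> bin-pair table.  Chromosome/
    class combinations with too few pairs are skipped with a warning.
    Returns the fits (2 per usable chromosome) and one combined normalized
    table tagged by class.
    """
    fits: list[RegressionFit] = []
    frames: list[pd.DataFrame] = []
    for chrom in tables:
        for cls in ("AND", "XOR"):
            df = tables[chrom].get(cls)
            if df is None or df.empty:
                continue
            try:
                fit, norm = normalize_chromosome(df, cls, chrom)
            except ValueError as exc:
                warnings.warn(f"skipping {cls}/{chrom}: {exc}", RuntimeWarning)
                continue
            fits.append(fit)
            frames.append(norm)
    if not frames:
        raise ValueError("no chromosome/class combination could be normalized")
    combined = pd.concat(frames, ignore_index=True)
    combined = combined.sort_values(
        ["chrom", "bin1", "bin2", "pair_class"], kind="mergesort"
    ).reset_index(drop=True)
    return fits, combined


def fit_summary_table(fits: list[RegressionFit]) -> pd.DataFrame:
    """One-row-per-fit summary (the AIC/BIC audit file)."""
    rows = []
    for f in fits:
        row = {
            "chrom": f.chrom,
            "class": f.pair_class,
            "n_obs": f.n_obs,
            "loglik": f.loglik,
            "aic": f.aic,
            "bic": f.bic,
            "converged": f.converged,
            "n_iter": f.n_iter,
        }
        for name, b in zip(["b0"] + COVARIATES, f.beta):
            row[f"beta_{name}"] = b
        rows.append(row)
    return pd.DataFrame(rows)
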