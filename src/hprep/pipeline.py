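"""In-memory orchestration of the full workflow.

Glue used by both the command-line interface and programmatic studies:
normalize every sample, build anchor-by-offset matrices on the union
anchor set, optionally tune the smoothing half-width, and produce the
pairwise score matrix.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .contact_matrix import AnchorOffsetMatrix, build_matrix
from .io_formats import AnchorSet, StudyConfig
from .normalization import RegressionFit, normalize_sample
from .reproducibility import ScoreMatrix, score_matrix, tune_smoothing
from .resampling import Tables

__all__ = ["normalize_study", "study_matrices", "run_study"]


def normalize_study(
    sample_tables: dict[str, Tables],
) -> tuple[dict[str, list[RegressionFit]], dict[str, pd.DataFrame]]:
    """Fit and normalize every sample; returns per-sample fits and combined tables."""
    fits: dict[str, list[RegressionFit]] = {}
    normalized: dict[str, pd.DataFrame] = {}
    for sid, tables in sample_tables.items():
        fits[sid], normalized[sid] = normalize_sample(tables)
    return fits, normalized


def study_matrices(
    normalized: dict[str, pd.DataFrame],
    union_anchors: AnchorSet,
    config: StudyConfig,
) -> dict[str, dict[str, AnchorOffsetMatrix]]:
    """Anchor-by-offset matrices per sample, all on the shared union anchor set."""
    return {
        sid: build_matrix(df, union_anchors, config) for sid, df in normalized.items()
    }


def run_study(
    sample_tables: dict[str, Tables],
    union_anchors: AnchorSet,
    config: StudyConfig,
    tuning_pair: tuple[str, str] | None = None,
) -> tuple[ScoreMatrix, int, dict[str, list[RegressionFit]]]:
    """Normalize, (optionally) tune smoothing, and score all sample pairs.

    If ``config.smoothing_d`` is ``"tune"``, the half-width is optimised on
    ``tuning_pair`` (default: the first two samples) and reused for every
    comparison.  Returns the score matrix, the smoothing half-width used,
    and the regression fits.
    """
    fits, normalized = normalize_study(sample_tables)
    mats = study_matrices(normalized, union_anchors, config)
    if config.smoothing_d == "tune":
        sids = list(sample_tables)
        a, b = tuning_pair if tuning_pair is not None else (sids[0], sids[1])
        d, _ = tune_smoothing(mats[a], mats[b], seed=config.seed)
    else:
        d = int(config.smoothing_d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scores = score_matrix(mats, d)
    return scores, d, fits
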