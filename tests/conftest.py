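import numpy as np
import pytest

from hprep.contact_matrix import AnchorOffsetMatrix
from hprep.synthetic_data import SimConfig, simulate_study


def make_matrix(values, chrom="sim1", resolution=10_000, anchors=None):
    """Wrap an N x m array (m even) into an AnchorOffsetMatrix."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    assert m % 2 == 0
    if anchors is None:
        anchors = np.arange(n, dtype=np.int64) * resolution
    return AnchorOffsetMatrix(
        chrom=chrom,
        anchors=np.asarray(anchors, dtype=np.int64),
        resolution=resolution,
        binning_distance=(m // 2) * resolution,
        values=values,
    )


def random_matrix_pair(rng, n=6, m=8, sparsity=0.4):
    """Two random matrices on a shared anchor set with sprinkled zeros."""
    a = rng.normal(1.0, 0.6, size=(n, m))
    b = 0.6 * a + rng.normal(0.0, 0.5, size=(n, m))
    a[rng.uniform(size=(n, m)) < sparsity] = 0.0
    b[rng.uniform(size=(n, m)) < sparsity] = 0.0
    return make_matrix(a), make_matrix(b)


@pytest.fixture(scope="session")
def tiny_study():
    """Small two-condition, two-replicate study reused by read-only tests."""
    return simulate_study(SimConfig(seed=11, n_chroms=1, n_bins=1200, depth=1e5))


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_study):
    """Normalized tables and matrices for the tiny study."""
    from hprep.pipeline import normalize_study, study_matrices

    tables = {sid: s.tables for sid, s in tiny_study.samples.items()}
    fits, normalized = normalize_study(tables)
    mats = study_matrices(normalized, tiny_study.union_anchors, tiny_study.study_config())
    return {"fits": fits, "normalized": normalized, "matrices": mats}
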