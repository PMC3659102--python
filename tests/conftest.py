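import numpy as np
import pytest

from nmfmcc import ExpressionMatrix, init_factors


@pytest.fixture
def tiny_tsv(tmp_path):
    """3-gene x 2-sample expression table on disk."""
    path = tmp_path / "tiny.tsv"
    path.write_text(
        "gene_id\tsampleA\tsampleB\n"
        "g1\t1\t2\n"
        "g2\t0\t3\n"
        "g3\t4\t0\n"
    )
    return path


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [0.0, 3.0], [4.0, 0.0]]),
        ["g1", "g2", "g3"],
        ["sampleA", "sampleB"],
    )


def random_instance(seed, D=12, N=8, K=3):
    """Random non-negative X with conforming positive factors."""
    rng = np.random.default_rng(seed)
    X = rng.random((D, N))
    H, W = init_factors(D, N, K, seed + 1, target_mean=float(X.mean()))
    return X, H, W
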