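"""Synthetic expression matrices with planted classes and outlier genes.

The generator emulates the structure of multi-class tumor expression data
as it matters to robust factorization: most genes behave similarly across
all samples, a small informative fraction is shifted upward in exactly one
sample class, and a controllable fraction of genes is corrupted wholesale
by heavy-tailed noise (whole rows, matching the per-gene granularity of the
correntropy weights).  Ground-truth class labels and gene masks come back
alongside the matrix, so clustering accuracy and implicit gene selection
are both directly measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, LabelVector

__all__ = ["SyntheticDataset", "generate"]


@dataclass
class SyntheticDataset:
    """A generated matrix with its ground truth.

    ``informative_mask`` marks class-discriminating genes and
    ``outlier_mask`` marks corrupted genes; the two are disjoint, the
    remaining genes are uninformative background.
    """

    X: ExpressionMatrix
    truth: LabelVector
    informative_mask: np.ndarray
    outlier_mask: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if np.any(self.informative_mask & self.outlier_mask):
            raise ValueError("informative and outlier masks overlap")


def generate(
    D: int = 500,
    N: int = 80,
    K: int = 4,
    frac_informative: float = 0.1,
    frac_outlier: float = 0.1,
    signal: float = 3.0,
    noise_sd: float = 0.5,
    outlier_scale: float = 5.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a D-gene x N-sample matrix with K planted sample classes.

    Construction
    ------------
    * Samples are split into K near-equal contiguous classes.
    * Every gene gets a baseline expression drawn uniform(1, 2).
    * ``ceil(frac_informative * D)`` informative genes, chosen at random and
      partitioned near-equally across the classes, have ``signal`` added in
      their class's samples only.
    * Gaussian noise with sd ``noise_sd`` is added everywhere, then values
      are truncated at zero to keep the matrix non-negative.
    * ``ceil(frac_outlier * D)`` genes drawn from the background are
      replaced entirely by heavy-tailed non-negative noise,
      ``outlier_scale * |t(df=3)|`` — the corrupted-row regime a robust
      loss is supposed to shrug off.

    Identical seeds give bit-identical datasets.
    """
    if not 0 < frac_informative < 1:
        raise ValueError(f"frac_informative must be in (0,1), got {frac_informative}")
    if not 0 <= frac_outlier < 1:
        raise ValueError(f"frac_outlier must be in [0,1), got {frac_outlier}")
    if K < 1 or K > N:
        raise ValueError(f"need 1 <= K <= N, got K={K}, N={N}")
    if signal <= 0 or noise_sd <= 0 or outlier_scale <= 0:
        raise ValueError("signal, noise_sd and outlier_scale must be positive")
    n_inf = math.ceil(frac_informative * D)
    n_out = math.ceil(frac_outlier * D)
    if n_inf < K:
        raise ValueError(
            f"{n_inf} informative genes cannot cover K={K} classes; "
            "increase D or frac_informative"
        )
    if n_inf + n_out > D:
        raise ValueError("informative and outlier fractions exceed the gene count")

    rng = np.random.default_rng(seed)
    classes = np.concatenate(
        [np.full(len(chunk), k) for k, chunk in enumerate(np.array_split(np.arange(N), K))]
    )

    perm = rng.permutation(D)
    inf_idx = perm[:n_inf]
    out_idx = perm[n_inf : n_inf + n_out]
    informative_mask = np.zeros(D, dtype=bool)
    informative_mask[inf_idx] = True
    outlier_mask = np.zeros(D, dtype=bool)
    outlier_mask[out_idx] = True

    baseline = rng.uniform(1.0, 2.0, size=D)
    M = np.repeat(baseline[:, None], N, axis=1)
    # partition informative genes across classes near-equally
    for k, gene_chunk in enumerate(np.array_split(inf_idx, K)):
        cols = classes == k
        for g in gene_chunk:
            M[g, cols] += signal

    X = M + rng.normal(0.0, noise_sd, size=(D, N))
    np.clip(X, 0.0, None, out=X)
    if n_out:
        X[out_idx] = outlier_scale * np.abs(rng.standard_t(3, size=(n_out, N)))

    matrix = ExpressionMatrix(
        X,
        [f"gene_{i + 1:04d}" for i in range(D)],
        [f"sample_{j + 1:03d}" for j in range(N)],
    )
    truth = LabelVector(matrix.sample_ids, [f"class_{k}" for k in classes])
    params = dict(
        D=D, N=N, K=K, frac_informative=frac_informative,
        frac_outlier=frac_outlier, signal=signal, noise_sd=noise_sd,
        outlier_scale=outlier_scale, seed=seed,
    )
    return SyntheticDataset(matrix, truth, informative_mask, outlier_mask, params)
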