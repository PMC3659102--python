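"""Gaussian-kernel correntropy utilities.

Correntropy is a kernelized similarity between paired observations,
V_sigma(x, y) = E[k_sigma(x - y)], estimated from a sample as the mean of
Gaussian kernel evaluations of the residuals.  Maximizing it (the maximum
correntropy criterion, MCC) behaves like a Welsch M-estimator: residuals
much larger than the bandwidth contribute almost nothing, which is what
makes the criterion robust to outliers.

In the factorization setting each gene d contributes a single residual
e_d^2 = sum_n (x_dn - (HW)_dn)^2, its squared l2 distance across samples,
and the objective is F(H, W) = sum_d exp(-e_d^2 / (2 sigma^2)).  The
half-quadratic auxiliary variable rho_d = -exp(-e_d^2 / (2 sigma^2)) turns
each conditional subproblem into weighted least squares with per-gene
weights -rho_d in (0, 1]: soft gene selection.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "gaussian_kernel_sq",
    "sample_correntropy",
    "cim",
    "row_squared_residuals",
    "mcc_objective",
    "update_bandwidth",
    "estep_rho",
    "BandwidthFloorWarning",
]


class BandwidthFloorWarning(RuntimeWarning):
    """Emitted when the adaptive bandwidth hits its positivity floor."""


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)


def gaussian_kernel_sq(z, sigma2: float):
    """Gaussian kernel of an already-squared argument: exp(-z / (2 sigma2)).

    ``z`` is a squared error (or array of them), so the kernel's usual
    ``(x - y)^2`` is supplied directly.  Returns values in (0, 1], equal to
    1 exactly when ``z == 0``, strictly decreasing in ``z``.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise ValueError("squared argument must be non-negative")
    out = np.exp(-z_arr / (2.0 * sigma2))
    return float(out) if np.isscalar(z) or z_arr.ndim == 0 else out


def sample_correntropy(x, y, sigma2: float) -> float:
    """Sample correntropy (1/I) sum_i k_sigma(x_i - y_i) of paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValueError("vectors must have at least one element")
    return float(np.mean(gaussian_kernel_sq((x - y) ** 2, sigma2)))


def cim(x, y, sigma2: float) -> float:
    """Correntropy induced metric between two equal-length vectors.

    CIM(x, y) = (k_sigma(0) - (1/D) sum_d k_sigma(e_d))^(1/2) with
    e_d = x_d - y_d.  Zero exactly when x == y; bounded above by 1.
    """
    v = sample_correntropy(x, y, sigma2)
    # clamp float round-off: k(0) = 1 >= v mathematically
    return float(np.sqrt(max(1.0 - v, 0.0)))


def row_squared_residuals(X, H, W) -> np.ndarray:
    """Per-gene squared residuals e_d^2 = sum_n (x_dn - (HW)_dn)^2."""
    Xv = _as_values(X)
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    if H.shape[0] != Xv.shape[0] or W.shape[1] != Xv.shape[1] or H.shape[1] != W.shape[0]:
        raise ValueError(
            f"non-conforming shapes: X {Xv.shape}, H {H.shape}, W {W.shape}"
        )
    resid = Xv - H @ W
    return np.einsum("dn,dn->d", resid, resid)


def mcc_objective(X, H, W, sigma2: float) -> float:
    """Correntropy objective F(H, W) = sum_d exp(-e_d^2 / (2 sigma2)).

    Lies in (0, D]; equals D (the number of genes) iff X == HW exactly.
    """
    return float(np.sum(gaussian_kernel_sq(row_squared_residuals(X, H, W), sigma2)))


def update_bandwidth(sq_residuals, theta: float, floor: float = 0.0) -> float:
    """Adaptive kernel bandwidth sigma^2 = (theta / (2D)) * sum_d e_d^2.

    ``theta`` scales the bandwidth and thereby the sparseness of the
    auxiliary weights: smaller theta makes the kernel narrower, so genes
    with above-average residuals are suppressed more aggressively.

    ``floor`` is the smallest admissible return value; it keeps sigma^2
    strictly positive when the factorization fits exactly.  Hitting the
    floor emits :class:`BandwidthFloorWarning`.
    """
    r = np.asarray(sq_residuals, dtype=float)
    if r.size < 1:
        raise ValueError("residual vector is empty")
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    sigma2 = theta / (2.0 * r.size) * float(np.sum(r))
    lo = max(floor, np.finfo(float).tiny)
    if sigma2 < lo:
        warnings.warn(
            f"adaptive bandwidth {sigma2:g} floored at {lo:g} "
            "(residuals are (near-)zero)",
            BandwidthFloorWarning,
            stacklevel=2,
        )
        return lo
    return sigma2


def estep_rho(sq_residuals, sigma2: float) -> np.ndarray:
    """Half-quadratic auxiliary weights rho_d = -exp(-e_d^2 / (2 sigma2)).

    Each rho_d lies in [-1, 0); -rho_d acts as the gene's weight in the
    conditional weighted-least-squares subproblems.  A perfectly fit gene
    gets weight 1; genes with large residuals (outliers) get weights near 0.
    """
    return -gaussian_kernel_sq(np.asarray(sq_residuals, dtype=float), sigma2)
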