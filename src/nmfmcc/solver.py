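"""Expectation conditional maximization solver for correntropy NMF.

The fitting loop alternates:

* **E-step** — from the current factors compute per-gene squared residuals,
  the adaptive bandwidth sigma^2 = (theta / 2D) sum_d e_d^2, and auxiliary
  weights rho_d = -exp(-e_d^2 / (2 sigma^2)).
* **CM-steps** — with rho fixed, minimize the weighted least-squares
  surrogate O(H, W) = Tr[(X - HW)^T diag(-rho) (X - HW)] by one
  multiplicative update of H, then one of W conditioned on the fresh H.

With rho fixed, O is nonincreasing under each update (auxiliary-function
argument, as for the classical multiplicative rules), which is the
monotonicity guarantee the tests assert.  The full correntropy objective F
is recorded in the trace for inspection but carries no per-iteration
guarantee, because sigma^2 changes between iterations.

Classical l2 and KL NMF (Lee-Seung multiplicative updates) are provided as
baselines behind the same configuration and result types; the l2 baseline
is exactly the correntropy solver with rho pinned at -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .correntropy import (
    estep_rho,
    mcc_objective,
    row_squared_residuals,
    update_bandwidth,
)
from .io import ExpressionMatrix, ValidationError

__all__ = [
    "SolverConfig",
    "FactorizationResult",
    "init_factors",
    "weighted_objective",
    "cm_update_H",
    "cm_update_W",
    "fit_nmf_mcc",
    "fit_baseline_nmf",
]


@dataclass(frozen=True)
class SolverConfig:
    """Settings shared by the correntropy solver and the baselines.

    Parameters
    ----------
    k
        Number of meta-samples (typically the number of expected classes);
        must satisfy 1 <= k <= min(n_genes, n_samples), checked at fit time.
    theta
        Bandwidth scale of the adaptive kernel; larger values widen the
        kernel and flatten the gene weights, smaller values sharpen the
        implicit gene selection.
    max_iter, tol
        Outer-loop budget and relative-change stopping threshold on the
        minimized objective.
    denom_guard
        Small constant added to multiplicative-update denominators; set to
        0 to study exact fixed points.
    seed
        Seeds the random factor initialization; identical configs and seeds
        give bit-identical runs.
    """

    k: int
    theta: float = 1.0
    max_iter: int = 500
    tol: float = 1e-6
    denom_guard: float = 1e-10
    seed: int = 0
    init: str = "uniform-scaled"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.tol < 0:
            raise ValueError(f"tol must be >= 0, got {self.tol}")
        if self.denom_guard < 0:
            raise ValueError(f"denom_guard must be >= 0, got {self.denom_guard}")
        if self.init != "uniform-scaled":
            raise ValueError(f"unknown init scheme {self.init!r}")


@dataclass
class FactorizationResult:
    """Fitted factors plus per-iteration diagnostics.

    ``H`` (genes x k) holds the meta-samples, ``W`` (k x samples) the
    codings clustered downstream.  ``rho`` are the final per-gene auxiliary
    weights (uniform -1 for the baselines); ``-rho`` is the gene's soft
    selection weight.  ``objective_trace`` has one row per outer iteration
    with the minimized objective after the E-step and after each CM update,
    plus the correntropy value F and sigma^2 for the correntropy loss.
    """

    H: np.ndarray
    W: np.ndarray
    rho: np.ndarray
    sigma2: float | None
    objective_trace: pd.DataFrame
    n_iter: int
    converged: bool
    loss: str
    theta: float
    seed: int
    gene_ids: list[str]
    sample_ids: list[str]


def init_factors(
    D: int, N: int, K: int, seed: int, target_mean: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Strictly positive random factors with mean(HW) matched to a target.

    Entries are uniform on (0, 1]; both factors are then rescaled by a
    common constant so that mean(HW) equals ``target_mean`` (the data mean,
    when called from the solvers), keeping early residuals on the data's
    scale regardless of K.
    """
    if not 1 <= K <= min(D, N):
        raise ValueError(f"K={K} out of range [1, min(D={D}, N={N})]")
    rng = np.random.default_rng(seed)
    # 1 - U[0,1) lies in (0, 1]: strictly positive, so no entry is absorbed at 0
    H = 1.0 - rng.random((D, K))
    W = 1.0 - rng.random((K, N))
    if target_mean > 0:
        scale = np.sqrt(target_mean / np.mean(H @ W))
        H *= scale
        W *= scale
    return H, W


def weighted_objective(X, H, W, rho) -> float:
    """Weighted least squares O = sum_d (-rho_d) sum_n (x_dn - (HW)_dn)^2.

    This is the quantity each CM update decreases while rho is held fixed;
    with rho = -1 everywhere it reduces to the classical l2 NMF objective.
    """
    rho = np.asarray(rho, dtype=float)
    resid2 = row_squared_residuals(X, H, W)
    if rho.shape != resid2.shape:
        raise ValueError(f"rho has shape {rho.shape}, expected {resid2.shape}")
    return float(np.sum(-rho * resid2))


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)


def cm_update_H(X, H, W, rho, denom_guard: float = 1e-10) -> np.ndarray:
    """Multiplicative update of the meta-sample matrix with W fixed:

    H <- H * (diag(-rho) X W^T) / (diag(-rho) H W W^T + guard)
    """
    Xv = _values(X)
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    w = -np.asarray(rho, dtype=float)[:, None]
    num = (w * Xv) @ W.T
    den = (w * H) @ (W @ W.T) + denom_guard
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(num == 0.0, 0.0, num / den)
    return H * ratio


def cm_update_W(X, H, W, rho, denom_guard: float = 1e-10) -> np.ndarray:
    """Multiplicative update of the coding matrix with H fixed:

    W <- W * (H^T diag(-rho) X) / (H^T diag(-rho) H W + guard)
    """
    Xv = _values(X)
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    w = -np.asarray(rho, dtype=float)[:, None]
    wH = w * H
    num = wH.T @ Xv
    den = (H.T @ wH) @ W + denom_guard
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(num == 0.0, 0.0, num / den)
    return W * ratio


def _as_expression(X) -> ExpressionMatrix:
    if isinstance(X, ExpressionMatrix):
        return X
    Xv = np.asarray(X, dtype=float)
    d, n = Xv.shape
    return ExpressionMatrix(
        Xv, [f"g{i}" for i in range(d)], [f"s{j}" for j in range(n)]
    )


def fit_nmf_mcc(X, config: SolverConfig) -> FactorizationResult:
    """Fit X ~ HW by maximizing Gaussian correntropy between X and HW.

    Each outer iteration runs the E-step (residuals -> sigma^2 -> rho) and
    one conditional update of H then of W.  Stops when the relative change
    of the weighted objective falls below ``config.tol`` or after
    ``config.max_iter`` iterations.
    """
    Xm = _as_expression(X)
    Xv = Xm.values
    D, N = Xv.shape
    if config.k > min(D, N):
        raise ValueError(f"k={config.k} exceeds min(D={D}, N={N})")
    H, W = init_factors(D, N, config.k, config.seed, target_mean=float(Xv.mean()))
    sigma_floor = 1e-12 * (1.0 + float(np.mean(Xv**2)))

    rows = []
    prev_obj = None
    converged = False
    sigma2 = sigma_floor
    rho = -np.ones(D)
    for it in range(config.max_iter):
        resid2 = row_squared_residuals(Xv, H, W)
        sigma2 = update_bandwidth(resid2, config.theta, floor=sigma_floor)
        rho = estep_rho(resid2, sigma2)
        obj_e = float(np.sum(-rho * resid2))
        H = cm_update_H(Xv, H, W, rho, config.denom_guard)
        obj_h = weighted_objective(Xv, H, W, rho)
        W = cm_update_W(Xv, H, W, rho, config.denom_guard)
        obj_w = weighted_objective(Xv, H, W, rho)
        rows.append(
            (it, obj_w, obj_e, obj_h, mcc_objective(Xv, H, W, sigma2), sigma2)
        )
        if prev_obj is not None and abs(prev_obj - obj_w) <= config.tol * max(
            prev_obj, np.finfo(float).tiny
        ):
            converged = True
            break
        prev_obj = obj_w
    # final weights reflect the returned factors
    resid2 = row_squared_residuals(Xv, H, W)
    sigma2 = update_bandwidth(resid2, config.theta, floor=sigma_floor)
    rho = estep_rho(resid2, sigma2)

    trace = pd.DataFrame(
        rows,
        columns=["iteration", "objective", "objective_estep",
                 "objective_after_h", "mcc", "sigma2"],
    )
    return FactorizationResult(
        H=H, W=W, rho=rho, sigma2=sigma2, objective_trace=trace,
        n_iter=len(rows), converged=converged, loss="mcc",
        theta=config.theta, seed=config.seed,
        gene_ids=Xm.gene_ids, sample_ids=Xm.sample_ids,
    )


def _kl_divergence(Xv: np.ndarray, HW: np.ndarray, guard: float) -> float:
    safe = HW + guard
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(Xv > 0, Xv * np.log(Xv / safe), 0.0)
    return float(np.sum(term - Xv + HW))


def fit_baseline_nmf(
    X, config: SolverConfig, loss: Literal["l2", "kl"] = "l2"
) -> FactorizationResult:
    """Classical multiplicative-update NMF minimizing the l2 or KL loss.

    Shares initialization, stopping rule and result type with
    :func:`fit_nmf_mcc`.  The returned ``rho`` is the uniform vector -1:
    every gene carries full weight.
    """
    if loss not in ("l2", "kl"):
        raise ValueError(f"loss must be 'l2' or 'kl', got {loss!r}")
    Xm = _as_expression(X)
    Xv = Xm.values
    D, N = Xv.shape
    if config.k > min(D, N):
        raise ValueError(f"k={config.k} exceeds min(D={D}, N={N})")
    H, W = init_factors(D, N, config.k, config.seed, target_mean=float(Xv.mean()))
    rho = -np.ones(D)
    guard = config.denom_guard

    rows = []
    prev_obj = None
    converged = False
    for it in range(config.max_iter):
        if loss == "l2":
            H = cm_update_H(Xv, H, W, rho, guard)
            obj_h = weighted_objective(Xv, H, W, rho)
            W = cm_update_W(Xv, H, W, rho, guard)
            obj = weighted_objective(Xv, H, W, rho)
        else:
            HW = H @ W
            H = H * ((Xv / (HW + guard)) @ W.T) / (W.sum(axis=1)[None, :] + guard)
            obj_h = _kl_divergence(Xv, H @ W, guard)
            HW = H @ W
            W = W * (H.T @ (Xv / (HW + guard))) / (H.sum(axis=0)[:, None] + guard)
            obj = _kl_divergence(Xv, H @ W, guard)
        rows.append((it, obj, np.nan, obj_h, np.nan, np.nan))
        if prev_obj is not None and abs(prev_obj - obj) <= config.tol * max(
            prev_obj, np.finfo(float).tiny
        ):
            converged = True
            break
        prev_obj = obj

    trace = pd.DataFrame(
        rows,
        columns=["iteration", "objective", "objective_estep",
                 "objective_after_h", "mcc", "sigma2"],
    )
    return FactorizationResult(
        H=H, W=W, rho=rho, sigma2=None, objective_trace=trace,
        n_iter=len(rows), converged=converged, loss=loss,
        theta=config.theta, seed=config.seed,
        gene_ids=Xm.gene_ids, sample_ids=Xm.sample_ids,
    )
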