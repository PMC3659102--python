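"""Clustering of coding-space representations and matched accuracy.

Samples are clustered by k-means on the columns of the coding matrix W
(each sample's K-dimensional coefficients over the meta-samples).  Cluster
labels are arbitrary, so accuracy is computed after optimally matching
predicted clusters to true classes: a one-to-one assignment maximizing the
contingency-table overlap, found with the Hungarian algorithm.  The
repeated-trial protocol refits from fresh random initializations and
reports the per-trial accuracies with their mean and standard deviation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .io import LabelVector
from .solver import FactorizationResult, SolverConfig, fit_baseline_nmf, fit_nmf_mcc

__all__ = [
    "ClusteringReport",
    "cluster_codings",
    "matched_accuracy",
    "run_trials",
    "write_clustering_report",
]


@dataclass
class ClusteringReport:
    """Outcome of one or more clustering trials.

    ``predicted``/``matching``/``matched_accuracy`` describe the best trial
    (highest accuracy); ``trial_accuracies`` holds every trial, summarized
    by ``mean_accuracy`` and ``std_accuracy`` (n-1 denominator, 0 for a
    single trial).
    """

    predicted: np.ndarray
    matched_accuracy: float
    matching: dict[int, str]
    trial_accuracies: list[float]
    mean_accuracy: float
    std_accuracy: float
    method: str = "mcc"
    results: list[FactorizationResult] | None = None


def cluster_codings(W, K: int, seed: int) -> np.ndarray:
    """k-means cluster the N samples by their K-dimensional codings.

    Uses K seeded k-means++ restarts; returns one of K integer labels per
    column of W.
    """
    W = np.asarray(W, dtype=float)
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > W.shape[1]:
        raise ValueError(f"K={K} exceeds the number of samples {W.shape[1]}")
    km = KMeans(n_clusters=K, n_init=max(K, 1), random_state=seed)
    return km.fit_predict(W.T)


def matched_accuracy(predicted, truth) -> tuple[float, dict[int, str]]:
    """Accuracy after optimal one-to-one cluster-to-class matching.

    Builds the contingency table between predicted clusters and true
    classes and solves the assignment problem maximizing the total overlap;
    the accuracy is the matched count over N.  Works whichever side has
    more distinct labels (unmatched clusters simply count as errors).
    Returns ``(accuracy, matching)`` where ``matching`` maps each matched
    predicted-cluster index to a true class label.
    """
    if isinstance(truth, LabelVector):
        true_codes = truth.codes
        class_names = truth.classes
    else:
        tv = LabelVector([f"s{i}" for i in range(len(truth))],
                         [str(t) for t in truth])
        true_codes = tv.codes
        class_names = tv.classes
    predicted = np.asarray(predicted)
    if predicted.shape[0] != true_codes.shape[0]:
        raise ValueError(
            f"{predicted.shape[0]} predictions for {true_codes.shape[0]} truths"
        )
    pred_values = list(dict.fromkeys(predicted.tolist()))
    pred_codes = np.array([pred_values.index(p) for p in predicted.tolist()])
    n_pred, n_true = len(pred_values), len(class_names)
    cont = np.zeros((n_pred, n_true), dtype=int)
    np.add.at(cont, (pred_codes, true_codes), 1)
    rows, cols = linear_sum_assignment(-cont)
    acc = float(cont[rows, cols].sum()) / len(predicted)
    matching = {pred_values[r]: class_names[c] for r, c in zip(rows, cols)}
    return acc, matching


def run_trials(
    X,
    truth: LabelVector,
    config: SolverConfig,
    n_trials: int,
    base_seed: int,
    method: str = "mcc",
    keep_results: bool = False,
) -> ClusteringReport:
    """Repeat fit -> cluster -> matched accuracy over fresh initializations.

    Trial t uses seed ``base_seed + t`` (t = 1..n_trials) for both the
    factorization and k-means, so a report is exactly reproducible from its
    base seed.  ``method`` selects the correntropy solver (``"mcc"``) or a
    baseline loss (``"l2"``/``"kl"``).
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if method not in ("mcc", "l2", "kl"):
        raise ValueError(f"unknown method {method!r}")
    accs: list[float] = []
    kept: list[FactorizationResult] = []
    best = None  # (acc, predicted, matching)
    for t in range(1, n_trials + 1):
        cfg = replace(config, seed=base_seed + t)
        if method == "mcc":
            res = fit_nmf_mcc(X, cfg)
        else:
            res = fit_baseline_nmf(X, cfg, loss=method)
        labels = cluster_codings(res.W, cfg.k, seed=base_seed + t)
        acc, matching = matched_accuracy(labels, truth)
        accs.append(acc)
        if keep_results:
            kept.append(res)
        if best is None or acc > best[0]:
            best = (acc, labels, matching)
    mean = float(np.mean(accs))
    std = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    return ClusteringReport(
        predicted=best[1],
        matched_accuracy=best[0],
        matching=best[2],
        trial_accuracies=accs,
        mean_accuracy=mean,
        std_accuracy=std,
        method=method,
        results=kept if keep_results else None,
    )


def write_clustering_report(
    report: ClusteringReport, out_dir: str | os.PathLike,
    config: SolverConfig | None = None,
) -> dict[str, str]:
    """Write the per-trial table and a summary block as delimited text."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "trials": os.path.join(out_dir, "trials.tsv"),
        "summary": os.path.join(out_dir, "report_summary.tsv"),
    }
    pd.DataFrame(
        {
            "trial": np.arange(1, len(report.trial_accuracies) + 1),
            "accuracy": report.trial_accuracies,
        }
    ).to_csv(paths["trials"], sep="\t", index=False)
    summary = {
        "method": report.method,
        "n_trials": len(report.trial_accuracies),
        "mean_accuracy": report.mean_accuracy,
        "std_accuracy": report.std_accuracy,
        "best_accuracy": report.matched_accuracy,
    }
    if config is not None:
        summary["K"] = config.k
        summary["theta"] = config.theta
    pd.Series(summary).to_csv(paths["summary"], sep="\t", header=False)
    return paths
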