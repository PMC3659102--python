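"""Expression-matrix containers and delimited-text input/output.

The package works on a genes-by-samples matrix: rows are genes (features),
columns are samples.  All values are non-negative expression levels.  Files
are plain delimited text: the header row carries sample identifiers, the
first column carries gene identifiers.  Orientation cannot be inferred from
a file, so it is a documented convention, not a runtime check.

Numbers are serialized with 17 significant digits, which is sufficient for
IEEE-754 doubles to round-trip exactly through decimal text.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "LabelVector",
    "read_expression_table",
    "write_expression_table",
    "read_labels",
    "write_labels",
    "write_factorization",
]

#: printf format giving exact decimal round-trips for float64
FLOAT_FMT = "%.17g"


class ValidationError(ValueError):
    """Raised when a matrix or label set violates its invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Non-negative D x N expression matrix with gene and sample ids.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_samples)``; every entry must be finite
        and >= 0.
    gene_ids
        ``n_genes`` unique row identifiers.
    sample_ids
        ``n_samples`` unique column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError(
                f"expression values must be 2-dimensional, got shape {self.values.shape}"
            )
        d, n = self.values.shape
        if d < 1 or n < 1:
            raise ValidationError("matrix must have at least one gene and one sample")
        if len(self.gene_ids) != d:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {d} rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        bad = ~np.isfinite(self.values)
        if bad.any():
            d_i, n_i = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[d_i]!r}, "
                f"sample {self.sample_ids[n_i]!r}"
            )
        neg = self.values < 0
        if neg.any():
            d_i, n_i = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative value {self.values[d_i, n_i]} at gene "
                f"{self.gene_ids[d_i]!r}, sample {self.sample_ids[n_i]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )


@dataclass
class LabelVector:
    """Per-sample class labels (e.g. cancer subtype annotations).

    Labels are arbitrary strings; :attr:`codes` maps them to 0-based integer
    codes in order of first appearance.
    """

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.sample_ids) != len(self.labels):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {len(self.labels)} labels"
            )
        if len(self.labels) < 1:
            raise ValidationError("label vector is empty")
        _check_unique(self.sample_ids, "sample")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        out: list[str] = []
        for l in self.labels:
            if l not in out:
                out.append(l)
        return out

    @property
    def codes(self) -> np.ndarray:
        """Integer codes (0-based, first-appearance order)."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[l] for l in self.labels], dtype=int)

    def aligned_to(self, sample_ids: Sequence[str]) -> "LabelVector":
        """Reorder labels to match ``sample_ids`` (e.g. a matrix's columns)."""
        lut = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in sample_ids if s not in lut]
        if missing:
            raise ValidationError(f"labels missing for samples: {missing[:5]}")
        return LabelVector(list(sample_ids), [lut[s] for s in sample_ids])


def read_expression_table(path: str | os.PathLike, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited genes-by-samples table.

    First column: gene ids.  Header row: sample ids.  Body: non-negative
    numbers.  Raises :class:`ValidationError` on negative, non-finite or
    duplicate-id content and a parse error naming the offending cell on
    non-numeric content.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )
    # numpy's strtod is correctly rounded; pandas' fast parser is not,
    # and exact decimal round-trips rely on it
    values = df.to_numpy(dtype=object).astype(np.float64)
    return ExpressionMatrix(
        values,
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
    )


def write_expression_table(
    matrix: ExpressionMatrix, path: str | os.PathLike, delimiter: str = "\t"
) -> None:
    """Write a matrix as delimited text at full float64 precision."""
    matrix.to_frame().to_csv(path, sep=delimiter, float_format=FLOAT_FMT,
                             index_label="gene_id")


def read_labels(path: str | os.PathLike, delimiter: str = "\t") -> LabelVector:
    """Read a two-column (sample_id, label) table with header."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: label file needs sample_id and label columns")
    return LabelVector(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_labels(labels: LabelVector, path: str | os.PathLike, delimiter: str = "\t") -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep=delimiter, index=False
    )


def write_factorization(result, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a factorization result as a directory of delimited tables.

    Emits ``H.tsv`` (genes x meta-samples), ``W.tsv`` (meta-samples x
    samples), ``gene_weights.tsv`` (per-gene auxiliary weight rho and the
    feature-selection weight -rho), ``trace.tsv`` (per-iteration objective
    values) and ``summary.json`` with run metadata.  Creates ``out_dir`` on
    demand and returns a name -> path mapping.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    k = result.H.shape[1]
    meta_ids = [f"meta_{i + 1}" for i in range(k)]
    paths: dict[str, str] = {}

    h_df = pd.DataFrame(result.H, index=result.gene_ids, columns=meta_ids)
    paths["H"] = os.path.join(out_dir, "H.tsv")
    h_df.to_csv(paths["H"], sep="\t", float_format=FLOAT_FMT, index_label="gene_id")

    w_df = pd.DataFrame(result.W, index=meta_ids, columns=result.sample_ids)
    paths["W"] = os.path.join(out_dir, "W.tsv")
    w_df.to_csv(paths["W"], sep="\t", float_format=FLOAT_FMT, index_label="meta_sample")

    gw = pd.DataFrame(
        {"rho": result.rho, "minus_rho": -result.rho}, index=result.gene_ids
    )
    paths["gene_weights"] = os.path.join(out_dir, "gene_weights.tsv")
    gw.to_csv(paths["gene_weights"], sep="\t", float_format=FLOAT_FMT,
              index_label="gene_id")

    paths["trace"] = os.path.join(out_dir, "trace.tsv")
    result.objective_trace.to_csv(paths["trace"], sep="\t",
                                  float_format=FLOAT_FMT, index=False)

    summary = {
        "loss": result.loss,
        "K": k,
        "theta": result.theta,
        "seed": result.seed,
        "n_iter": result.n_iter,
        "converged": bool(result.converged),
        "final_objective": float(result.objective_trace["objective"].iloc[-1]),
        "sigma2": None if result.sigma2 is None else float(result.sigma2),
        "n_genes": len(result.gene_ids),
        "n_samples": len(result.sample_ids),
    }
    paths["summary"] = os.path.join(out_dir, "summary.json")
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
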