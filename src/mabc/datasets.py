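"""Labeled expression-matrix container and readers.

A dataset is a samples x genes matrix of expression intensities plus one
categorical class label per sample (the "diagnosis").  Files follow the
layout common to public microarray collections: each row is a sample, the
first column (configurable) is the diagnosis and the remaining columns are
genes.  CSV/TSV and MATLAB ``.mat`` encodings are supported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import loadmat

__all__ = ["ExpressionDataset", "read_dataset", "write_dataset_csv"]


@dataclass
class ExpressionDataset:
    """Expression values with per-sample class labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Expression intensities (dimensionless).
    labels : ndarray of shape (n_samples,)
        Integer class codes ``0..C-1``, assigned in order of first
        appearance of the original label values.
    gene_ids : list of str
        One identifier per gene, order matching the columns of ``values``.
    label_names : list
        Original label value for each class code.
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: list = field(default_factory=list)
    label_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        n, g = self.values.shape
        if len(self.labels) != n:
            raise ValueError(f"labels has length {len(self.labels)}, expected {n} samples")
        if not self.gene_ids:
            self.gene_ids = [f"g{j}" for j in range(g)]
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match the number of genes")
        if self.labels.dtype.kind not in "iu" or not self.label_names:
            codes, names = _encode_labels(self.labels)
            self.labels = codes
            self.label_names = names
        if self.n_classes < 2:
            raise ValueError("dataset must contain at least 2 classes")
        counts = np.bincount(self.labels, minlength=self.n_classes)
        if (counts == 0).any():
            raise ValueError("every class must have at least one sample")
        if np.isnan(self.values).any():
            raise ValueError(
                "dataset contains missing expression values; "
                "clean the file or load with impute='mean'"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.label_names)

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset_genes(self, indices) -> "ExpressionDataset":
        """New dataset restricted to ``indices``, order preserved."""
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            values=self.values[:, indices],
            labels=self.labels.copy(),
            gene_ids=[self.gene_ids[j] for j in indices],
            label_names=list(self.label_names),
        )


def _encode_labels(raw):
    """Map arbitrary label values to 0..C-1 in order of first appearance."""
    raw = np.asarray(raw)
    names: list = []
    seen: dict = {}
    codes = np.empty(len(raw), dtype=int)
    for i, v in enumerate(raw):
        key = v.item() if hasattr(v, "item") else v
        if key not in seen:
            seen[key] = len(names)
            names.append(key)
        codes[i] = seen[key]
    return codes, names


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mat":
        return "mat"
    if ext == ".tsv":
        return "tsv"
    return "csv"


def read_dataset(path, format=None, label_column=0, header="auto", impute=None):
    """Load an expression dataset from delimited text or a MATLAB matrix.

    Parameters
    ----------
    path : str
        File to read.
    format : {'csv', 'tsv', 'mat'}, optional
        Inferred from the extension when omitted.
    label_column : int, default 0
        Index of the diagnosis column; all other columns are genes.
    header : {'auto', True, False}
        Whether the first text row carries gene identifiers.  ``'auto'``
        treats it as a header when any non-label cell is non-numeric.
    impute : {None, 'mean'}
        Missing-value policy.  ``None`` rejects files with missing cells;
        ``'mean'`` replaces them with the per-gene mean.

    Returns
    -------
    ExpressionDataset
        Gene order preserved from the file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _infer_format(str(path))
    if fmt in ("csv", "tsv"):
        values, labels, gene_ids = _read_delimited(path, fmt, label_column, header)
    elif fmt == "mat":
        values, labels, gene_ids = _read_mat(path, label_column)
    else:
        raise ValueError(f"unsupported format: {fmt!r}")

    if np.isnan(values).any():
        if impute == "mean":
            col_mean = np.nanmean(values, axis=0)
            nan_r, nan_c = np.nonzero(np.isnan(values))
            values[nan_r, nan_c] = col_mean[nan_c]
        else:
            raise ValueError(
                f"{path}: missing expression values found "
                "(pass impute='mean' to fill them with per-gene means)"
            )
    return ExpressionDataset(values=values, labels=labels, gene_ids=gene_ids)


def _read_delimited(path, fmt, label_column, header):
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a label column plus at least one gene column")
    if label_column >= df.shape[1]:
        raise ValueError(f"{path}: label column {label_column} not present")

    gene_cols = [c for c in range(df.shape[1]) if c != label_column]
    has_header = header is True
    if header == "auto":
        first = df.iloc[0, gene_cols]
        has_header = pd.to_numeric(first, errors="coerce").isna().any()
    if has_header:
        gene_ids = [str(df.iloc[0, c]) for c in gene_cols]
        df = df.iloc[1:].reset_index(drop=True)
    else:
        gene_ids = [f"g{j}" for j in range(len(gene_cols))]
    if df.empty:
        raise ValueError(f"{path}: no sample rows")

    expr = df[gene_cols].apply(pd.to_numeric, errors="coerce")
    raw = df[gene_cols].to_numpy()
    bad = expr.isna().to_numpy() & (raw != "") & ~pd.isna(raw)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric expression value {raw[r, c]!r} "
            f"at row {r}, gene column {gene_cols[c]}"
        )
    labels = df[label_column].to_numpy()
    return expr.to_numpy(dtype=float), labels, gene_ids


def _read_mat(path, label_column):
    contents = loadmat(path)
    matrices = {
        k: v
        for k, v in contents.items()
        if not k.startswith("__") and isinstance(v, np.ndarray) and v.ndim == 2
        and v.dtype.kind in "fiu" and min(v.shape) >= 2
    }
    if len(matrices) != 1:
        raise ValueError(
            f"{path}: expected exactly one 2-D numeric matrix variable, "
            f"found {sorted(matrices) or 'none'}"
        )
    (mat,) = matrices.values()
    mat = np.asarray(mat, dtype=float)
    labels = mat[:, label_column]
    values = np.delete(mat, label_column, axis=1)
    gene_ids = [f"g{j}" for j in range(values.shape[1])]
    return values, labels, gene_ids


def write_dataset_csv(dataset: ExpressionDataset, path, header=True) -> None:
    """Write a dataset in the delimited layout accepted by :func:`read_dataset`."""
    labels = [dataset.label_names[c] for c in dataset.labels]
    df = pd.DataFrame(dataset.values, columns=dataset.gene_ids)
    df.insert(0, "diagnosis", labels)
    df.to_csv(path, index=False, header=header)
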