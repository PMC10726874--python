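"""Expression containers, normalization, and filtering.

The pipeline's in-memory unit is :class:`ExpressionStudy`: a gene x sample
matrix of expression values on a log-like scale together with per-sample
metadata (age in years, sex coded 0/1, tissue label, case/control/healthy
condition, dataset id).  Normalization supports the three platform branches
used upstream: quantile normalization (microarray), upper-quartile scaling
(RNA-seq), and a calibrated generalized-log transform (proteomics).
Low-coverage and non-protein-coding genes are dropped by explicit filters.

All operations preserve sample order and are idempotent where that is
meaningful (filters, quantile normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionStudy",
    "quantile_normalize",
    "upper_quartile_normalize",
    "vsn_transform",
    "filter_zero_coverage",
    "filter_protein_coding",
    "read_expression_tsv",
    "write_expression_tsv",
]

#: columns every sample-metadata frame must carry
METADATA_COLUMNS = ("sample_id", "age", "sex", "tissue", "condition", "dataset_id")

ALLOWED_CONDITIONS = frozenset({"case", "control", "healthy"})
ALLOWED_PLATFORMS = frozenset({"rnaseq", "microarray", "proteomics"})


class PreprocessError(ValueError):
    """Raised when an expression study violates an operation's contract."""


@dataclass
class ExpressionStudy:
    """A gene x sample expression matrix with aligned sample metadata.

    Parameters
    ----------
    matrix
        Genes in rows (index = gene ids), samples in columns (column
        labels = sample ids).  Values must be finite.
    samples
        One row per sample, columns as in :data:`METADATA_COLUMNS`, in the
        same order as the matrix columns.
    platform
        One of ``rnaseq``, ``microarray``, ``proteomics``.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    platform: str = "rnaseq"

    def __post_init__(self) -> None:
        if self.platform not in ALLOWED_PLATFORMS:
            raise PreprocessError(f"unknown platform {self.platform!r}")
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()].tolist()
            raise PreprocessError(f"duplicate gene ids: {dup[:5]}")
        if self.matrix.shape[1] != len(self.samples):
            raise PreprocessError(
                f"matrix has {self.matrix.shape[1]} columns but metadata has "
                f"{len(self.samples)} rows"
            )
        missing = set(METADATA_COLUMNS) - set(self.samples.columns)
        if missing:
            raise PreprocessError(f"metadata missing columns {sorted(missing)}")
        bad = set(self.samples["condition"]) - ALLOWED_CONDITIONS
        if bad:
            raise PreprocessError(f"unknown condition labels {sorted(bad)}")
        if (self.samples["age"] < 0).any():
            raise PreprocessError("negative ages in metadata")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise PreprocessError("non-finite expression values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def with_matrix(self, matrix: pd.DataFrame) -> "ExpressionStudy":
        return replace(self, matrix=matrix)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Force every sample onto the common (row-mean) quantile distribution.

    After the transform every column holds the identical sorted value
    multiset: the i-th order statistic of each column is replaced by the mean
    of the i-th order statistics across columns.  Tied values receive the
    mean of the row means at the tied positions (rank-average convention).
    """
    X = study.matrix.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise PreprocessError("quantile normalization needs at least 2 samples")
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    ranks = pd.DataFrame(X).rank(axis=0, method="average").to_numpy()
    out = np.interp(ranks, np.arange(1, n_genes + 1), mean_sorted)
    return study.with_matrix(
        pd.DataFrame(out, index=study.matrix.index, columns=study.matrix.columns)
    )


def upper_quartile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Scale each sample so its upper quartile of nonzero values matches the
    across-sample mean upper quartile."""
    X = study.matrix.to_numpy(dtype=float)
    uqs = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        nz = X[:, j][X[:, j] != 0]
        uq = np.percentile(nz, 75) if nz.size else 0.0
        if uq <= 0:
            sample = study.samples["sample_id"].iloc[j]
            raise PreprocessError(
                f"sample {sample!r} has non-positive upper quartile; cannot scale"
            )
        uqs[j] = uq
    target = uqs.mean()
    out = X * (target / uqs)
    return study.with_matrix(
        pd.DataFrame(out, index=study.matrix.index, columns=study.matrix.columns)
    )


def vsn_transform(study: ExpressionStudy) -> ExpressionStudy:
    """Variance-stabilizing generalized-log transform for proteomics.

    Each sample is affinely calibrated against the reference distribution
    (the row mean of sorted columns) by least squares, then passed through
    ``asinh`` scaled to base-2 logs, so differences between large values
    approach log2 fold changes.  The transform is monotone per sample.
    """
    if study.platform != "proteomics":
        raise PreprocessError("vsn_transform expects a proteomics study")
    X = study.matrix.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    ref_var = ref.var()
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if ref_var > 0:
            srt = np.sort(col)
            b = np.cov(srt, ref, bias=True)[0, 1] / ref_var
            if b <= 0:
                b = 1.0
        else:  # degenerate (constant) reference
            b = 1.0
        a = col.mean() - b * ref.mean()
        out[:, j] = np.arcsinh((col - a) / b) / np.log(2.0)
    return study.with_matrix(
        pd.DataFrame(out, index=study.matrix.index, columns=study.matrix.columns)
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_zero_coverage(
    study: ExpressionStudy, max_zero_fraction: float = 0.25
) -> ExpressionStudy:
    """Drop genes whose value is exactly zero in >= ``max_zero_fraction`` of
    samples (default: a quarter).  Survivor order is preserved."""
    zero_frac = (study.matrix == 0).mean(axis=1)
    keep = zero_frac < max_zero_fraction
    return study.with_matrix(study.matrix.loc[keep])


def filter_protein_coding(
    study: ExpressionStudy, annotation: Mapping[str, str]
) -> ExpressionStudy:
    """Keep only genes annotated ``protein_coding``; genes missing from the
    annotation are dropped."""
    if not annotation:
        raise PreprocessError("empty biotype annotation")
    keep = [g for g in study.gene_ids if annotation.get(g) == "protein_coding"]
    if not keep:
        warnings.warn("no protein-coding genes retained", stacklevel=2)
    return study.with_matrix(study.matrix.loc[keep])


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_expression_tsv(study: ExpressionStudy, matrix_path, metadata_path) -> None:
    """Write the matrix (gene rows, sample columns) and metadata as TSV."""
    study.matrix.to_csv(matrix_path, sep="\t", index_label="gene_id")
    study.samples.to_csv(metadata_path, sep="\t", index=False)


def read_expression_tsv(matrix_path, metadata_path, platform: str = "rnaseq") -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(metadata_path, sep="\t")
    return ExpressionStudy(matrix=matrix, samples=samples, platform=platform)
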