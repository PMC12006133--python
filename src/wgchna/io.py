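"""Reading, validation, quality filtering and standardization of expression data.

The central container is :class:`ExpressionMatrix`, a genes x samples real
matrix with ordered, unique gene and sample identifiers.  Trait tables
(:class:`TraitTable`) hold per-sample covariates, with categorical columns
one-hot expanded so that every column is numeric.

Missing values are represented as NaN throughout.  The intended preprocessing
order is ``filter_genes`` -> ``impute_missing`` -> ``standardize``; after
standardization every gene row has mean 0 and population standard deviation 1,
which downstream code relies on (the mean of z_i * z_j over samples is then
exactly the Pearson correlation of genes i and j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: cell contents accepted as explicit missing markers (any other non-numeric
#: cell also becomes missing, with the same NaN representation)
MISSING_MARKERS = ("", "NA", "NaN", "nan")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with identifiers.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``; NaN marks missing.
    gene_ids, sample_ids
        Ordered unique identifiers matching the matrix dimensions.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} identifiers: {sorted(dupes)}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.gene_ids), list(self.sample_ids))


@dataclass
class TraitTable:
    """Samples x traits numeric table aligned to an :class:`ExpressionMatrix`.

    ``encoding_map`` records, for each original categorical column, the ordered
    levels that were expanded into one-hot columns (all levels kept).
    """

    values: np.ndarray
    trait_ids: list[str]
    sample_ids: list[str]
    encoding_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.trait_ids)):
            raise ValueError("trait table shape does not match identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait table contains non-finite values after encoding")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.trait_ids)


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in ids:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def read_expression(
    path: str | Path,
    genes_in_rows: bool = True,
    delimiter: str = "\t",
) -> ExpressionMatrix:
    """Parse a delimited expression file into an :class:`ExpressionMatrix`.

    The first column holds row identifiers and the header row holds column
    identifiers.  By default rows are genes; pass ``genes_in_rows=False`` for
    the transposed layout.  Non-numeric cells (including the accepted missing
    markers) become NaN.
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0, keep_default_na=False)
    frame = frame.apply(
        lambda col: pd.to_numeric(
            col.replace(list(MISSING_MARKERS), np.nan), errors="coerce"
        )
    )
    if not genes_in_rows:
        frame = frame.T
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    return ExpressionMatrix.from_frame(frame)


def write_expression(X: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write the matrix with full round-trip precision (repr format)."""
    X.to_frame().to_csv(path, sep=delimiter, float_format="%.17g")


def filter_genes(
    X: ExpressionMatrix,
    max_missing_frac: float = 0.2,
    min_variance: float = 0.0,
) -> ExpressionMatrix:
    """Drop low-quality genes.

    A gene is removed when its missing fraction exceeds ``max_missing_frac``
    or when its variance over observed entries is <= ``min_variance``
    (population variance, divisor n).  Survivors keep their original order.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    missing = np.isnan(X.values)
    miss_frac = missing.mean(axis=1)
    with np.errstate(invalid="ignore"):
        variance = np.nanvar(X.values, axis=1)
    variance = np.where(np.isnan(variance), 0.0, variance)
    drop_missing = miss_frac > max_missing_frac
    drop_var = variance <= min_variance
    keep = ~(drop_missing | drop_var)
    logger.info(
        "filter_genes: removed %d genes for missingness > %.3g, "
        "%d for variance <= %.3g (%d survive of %d)",
        int(drop_missing.sum()), max_missing_frac,
        int((drop_var & ~drop_missing).sum()), min_variance,
        int(keep.sum()), X.n_genes,
    )
    if not keep.any():
        raise ValueError("all genes removed by quality filtering")
    return ExpressionMatrix(
        X.values[keep], [g for g, k in zip(X.gene_ids, keep) if k], list(X.sample_ids)
    )


def impute_missing(X: ExpressionMatrix, method: str = "gene_median") -> ExpressionMatrix:
    """Replace missing entries by the gene's median over observed entries."""
    if method != "gene_median":
        raise ValueError(f"unknown imputation method: {method!r}")
    values = X.values.copy()
    missing = np.isnan(values)
    if not missing.any():
        return X.copy()
    all_missing = missing.all(axis=1)
    if all_missing.any():
        bad = [g for g, b in zip(X.gene_ids, all_missing) if b]
        raise ValueError(f"genes with no observed values (filter first): {bad}")
    medians = np.nanmedian(values, axis=1)
    rows = np.where(missing.any(axis=1))[0]
    for i in rows:
        values[i, np.isnan(values[i])] = medians[i]
    return ExpressionMatrix(values, list(X.gene_ids), list(X.sample_ids))


def standardize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row: mean 0, population standard deviation 1.

    The population convention (divisor n) makes the per-sample product of two
    standardized genes average exactly to their Pearson correlation, which the
    hypergraph membership rule exploits.
    """
    if np.isnan(X.values).any():
        raise ValueError("standardize requires a complete matrix; impute first")
    mean = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, keepdims=True)  # ddof=0
    zero = np.where(sd[:, 0] == 0)[0]
    if zero.size:
        bad = [X.gene_ids[i] for i in zero]
        raise ValueError(f"zero-variance genes cannot be standardized: {bad}")
    return ExpressionMatrix((X.values - mean) / sd, list(X.gene_ids), list(X.sample_ids))


def read_traits(
    path: str | Path,
    expression: ExpressionMatrix,
    delimiter: str = "\t",
) -> TraitTable:
    """Read a samples x traits table and align it to ``expression``.

    Numeric columns pass through; categorical columns are one-hot encoded
    keeping every level (one 0/1 column per level, named ``trait=level``).
    The sample sets must match exactly; rows are reordered to the expression
    sample order, never silently dropped.
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    frame.index = frame.index.astype(str)
    extra = [s for s in frame.index if s not in set(expression.sample_ids)]
    absent = [s for s in expression.sample_ids if s not in set(frame.index)]
    if extra or absent:
        raise ValueError(
            f"trait/expression sample mismatch: traits-only={extra}, expression-only={absent}"
        )
    frame = frame.loc[expression.sample_ids]

    columns: list[pd.Series] = []
    encoding_map: dict[str, list[str]] = {}
    for name in frame.columns:
        col = frame[name]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().all():
            columns.append(numeric.astype(float).rename(str(name)))
        else:
            levels = sorted(col.astype(str).unique())
            encoding_map[str(name)] = levels
            for level in levels:
                columns.append(
                    (col.astype(str) == level).astype(float).rename(f"{name}={level}")
                )
    encoded = pd.concat(columns, axis=1)
    return TraitTable(
        encoded.to_numpy(dtype=float),
        list(encoded.columns),
        list(encoded.index),
        encoding_map,
    )
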