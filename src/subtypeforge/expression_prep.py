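"""Expression-matrix input and preprocessing.

Matrices are held as :class:`pandas.DataFrame` objects with genes as rows
(index = gene identifiers) and samples as columns (header = sample
identifiers), on the log2 scale.  Preprocessing before subtype discovery is
gene median centering followed by selection of the most variable genes by
(unscaled) median absolute deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "median_center_genes",
    "gene_mad",
    "select_top_variable_genes",
]


def read_expression_matrix(path, impute_missing: bool = False) -> pd.DataFrame:
    """Read a gene x sample TSV expression matrix and validate it.

    The file must have a header row of sample ids and a first column of gene
    ids.  Duplicate gene or sample ids and non-numeric cells are rejected.
    Empty cells are rejected unless ``impute_missing`` is set, in which case
    they are filled with the gene's median over the non-missing samples.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene id(s): {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"duplicate sample id(s): {dups}")
    values = df.apply(pd.to_numeric, errors="coerce")
    nonnum = values.isna() & df.notna()
    empty = df.isna()
    if nonnum.any().any():
        g, s = _first_true(nonnum)
        cell = df.loc[g, s]
        if str(cell).strip() != "":
            raise ParseError(f"non-numeric cell at gene {g!r}, sample {s!r}: {cell!r}")
    if (empty | nonnum).any().any():
        if not impute_missing:
            g, s = _first_true(empty | nonnum)
            raise ParseError(f"missing value at gene {g!r}, sample {s!r} (set impute_missing to fill)")
        med = values.median(axis=1)
        values = values.apply(lambda row: row.fillna(med[row.name]), axis=1)
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ParseError("non-finite values in expression matrix")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return values.astype(float)


def _first_true(mask: pd.DataFrame):
    stacked = mask.stack()
    idx = stacked[stacked].index[0]
    return idx[0], idx[1]


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def median_center_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's median so every row has median exactly 0."""
    if matrix.empty:
        raise DataError("empty expression matrix")
    return matrix.sub(matrix.median(axis=1), axis=0)


def gene_mad(matrix: pd.DataFrame) -> pd.Series:
    """Per-gene unscaled median absolute deviation across samples.

    ``score_g = median_s |x_gs - median_s(x_gs)|``.  No Gaussian consistency
    factor is applied: only the ranking is used downstream and scaling is
    rank-invariant.
    """
    if matrix.shape[1] < 2:
        raise DataError("MAD requires at least 2 samples")
    centered = matrix.sub(matrix.median(axis=1), axis=0)
    return centered.abs().median(axis=1)


def select_top_variable_genes(matrix: pd.DataFrame, n: int) -> pd.DataFrame:
    """Restrict to the ``n`` genes with largest MAD.

    Original gene order is preserved within the selection.  Ties at the
    cutoff are broken by gene-id lexicographic order so the selection is
    deterministic across platforms.
    """
    if n > matrix.shape[0]:
        raise DataError(f"requested {n} genes but matrix has {matrix.shape[0]}")
    mad = gene_mad(matrix)
    order = sorted(matrix.index, key=lambda g: (-mad[g], str(g)))
    keep = set(order[:n])
    return matrix.loc[[g for g in matrix.index if g in keep]]
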