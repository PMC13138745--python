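"""Gene x feature tables: reading, validation, imputation, normalization.

The central container is :class:`FeatureTable`, a thin wrapper around a
pandas DataFrame (rows = genes, columns = features) that additionally tracks
each feature's omics category (Mutation, Genomics, Transcriptomics,
Epigenetics) and its value kind (``numeric`` or ``count``).  The value kind
decides the imputation rule: numeric features take the column median of the
observed entries, count features take zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "FeatureTable",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "impute_missing",
    "zscore_normalize",
    "subset_features",
]

CATEGORIES = ("Mutation", "Genomics", "Transcriptomics", "Epigenetics")

#: strings treated as missing when reading delimited text
NA_MARKERS = ("", "NA", "NaN", "nan", "na")


class ValidationError(ValueError):
    """Raised when an input table violates the container's invariants."""


@dataclass
class FeatureTable:
    """Genes x features numeric matrix with category and value-kind metadata.

    Parameters
    ----------
    df : pandas.DataFrame
        Numeric frame indexed by unique gene symbols, columns are unique
        feature names.  Missing entries are NaN.
    categories : dict
        Maps each feature name to one of :data:`CATEGORIES`.  Features left
        unmapped default to ``"Genomics"``.
    value_kind : dict
        Maps each feature name to ``"numeric"`` or ``"count"``; default
        ``"numeric"``.
    """

    df: pd.DataFrame
    categories: dict[str, str] = field(default_factory=dict)
    value_kind: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.df.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene identifier: {dup!r}")
        if self.df.columns.has_duplicates:
            dup = self.df.columns[self.df.columns.duplicated()][0]
            raise ValidationError(f"duplicate feature name: {dup!r}")
        self.categories = {
            f: self.categories.get(f, "Genomics") for f in self.df.columns
        }
        for f, c in self.categories.items():
            if c not in CATEGORIES:
                raise ValidationError(f"unknown category {c!r} for feature {f!r}")
        self.value_kind = {
            f: self.value_kind.get(f, "numeric") for f in self.df.columns
        }
        for f, k in self.value_kind.items():
            if k not in ("numeric", "count"):
                raise ValidationError(f"unknown value kind {k!r} for feature {f!r}")

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.df.shape[0]

    @property
    def n_features(self) -> int:
        return self.df.shape[1]

    def has_missing(self) -> bool:
        return bool(self.df.isna().any().any())

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.df.copy(), dict(self.categories), dict(self.value_kind)
        )

    def _with_df(self, df: pd.DataFrame) -> "FeatureTable":
        cols = list(df.columns)
        return FeatureTable(
            df,
            {f: self.categories[f] for f in cols},
            {f: self.value_kind[f] for f in cols},
        )


def read_feature_table(path, category_map: dict | None = None) -> FeatureTable:
    """Read a delimited gene x feature table.

    The first column holds gene identifiers; every other column must be
    numeric, with empty cells or ``NA`` treated as missing.  The delimiter is
    sniffed between tab and comma.  ``category_map`` optionally maps feature
    names to ``{"category": ..., "value_kind": ...}`` dicts (or to a bare
    category string).
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=list(NA_MARKERS),
        keep_default_na=False, dtype=str,
    )
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene identifier: {dup!r}")
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric value in column {col!r}, row {gene!r}"
            ) from None
    categories: dict[str, str] = {}
    value_kind: dict[str, str] = {}
    for f, entry in (category_map or {}).items():
        if isinstance(entry, str):
            categories[f] = entry
        else:
            if "category" in entry:
                categories[f] = entry["category"]
            if "value_kind" in entry:
                value_kind[f] = entry["value_kind"]
    return FeatureTable(numeric, categories, value_kind)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a tab-delimited table (missing entries as empty cells)."""
    out = table.df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="")


def impute_missing(table: FeatureTable) -> FeatureTable:
    """Fill missing entries: column median for numeric, zero for counts.

    Numeric columns with no observed value at all are dropped with a
    warning — a median is undefined there and zero-filling would fabricate
    signal.  Observed entries are never altered, so the operation is
    idempotent.
    """
    df = table.df.copy()
    drop: list[str] = []
    for col in df.columns:
        if table.value_kind[col] == "count":
            df[col] = df[col].fillna(0.0)
        else:
            observed = df[col].dropna()
            if observed.empty:
                drop.append(col)
            else:
                df[col] = df[col].fillna(float(observed.median()))
    if drop:
        warnings.warn(
            f"dropping all-missing numeric feature(s): {', '.join(drop)}",
            UserWarning,
            stacklevel=2,
        )
        df = df.drop(columns=drop)
    return table._with_df(df)


def zscore_normalize(table: FeatureTable) -> FeatureTable:
    """Z-score each feature column: (x - mean) / sd with population sd.

    Constant columns map to all-zeros rather than NaN so that downstream
    kernels stay finite.  Requires a fully imputed table.
    """
    if table.has_missing():
        raise ValidationError(
            "missing values present; run impute_missing before zscore_normalize"
        )
    x = table.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # ddof=0
    centered = x - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    df = pd.DataFrame(z, index=table.df.index, columns=table.df.columns)
    return table._with_df(df)


def subset_features(table: FeatureTable, selector) -> FeatureTable:
    """Restrict the table to one omics category or an explicit feature list.

    ``selector`` is either a category name from :data:`CATEGORIES` or an
    iterable of feature names.  Gene order is unchanged.
    """
    if isinstance(selector, str):
        if selector not in CATEGORIES:
            raise ValidationError(
                f"unknown category {selector!r}; expected one of {CATEGORIES}"
            )
        cols = [f for f in table.feature_names if table.categories[f] == selector]
    else:
        cols = list(selector)
        unknown = [f for f in cols if f not in table.df.columns]
        if unknown:
            raise ValidationError(f"unknown feature(s): {', '.join(map(str, unknown))}")
    if not cols:
        raise ValidationError(f"selector {selector!r} selects no features")
    return table._with_df(table.df[cols])
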