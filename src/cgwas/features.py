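"""Phenotype table -> numeric feature matrix for clustering.

Processing order: categorical variables are dummy-encoded first (a missing
category is its own explicit level), numeric columns are mean-imputed, then
every column is z-standardized and constant columns are dropped. One-hot is
full (not k-1): the consumer is a clustering model, not a regression, so
collinearity is harmless and symmetry across levels is preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ID_COLUMN = "sample_id"


@dataclass
class FeatureMatrix:
    """Dense numeric design matrix with column provenance."""

    sample_ids: list
    X: np.ndarray  # (n_samples, n_features) float64, no NaN
    columns: list[str]
    #: per column: (source variable, level or None for numeric)
    provenance: list[tuple]

    @property
    def n_samples(self):
        return self.X.shape[0]

    @property
    def n_features(self):
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, ID_COLUMN, self.sample_ids)
        return df


def mean_impute(columns: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing cell by its column mean over observed entries.

    All-missing columns are dropped with a warning (their mean is undefined).
    """
    out = columns.copy()
    dead = [c for c in out.columns if out[c].notna().sum() == 0]
    if dead:
        warnings.warn(f"dropping all-missing column(s): {dead}")
        out = out.drop(columns=dead)
    return out.fillna(out.mean())


def split_columns(table: pd.DataFrame):
    """(numeric column names, categorical column names), excluding the id."""
    num, cat = [], []
    for c in table.columns:
        if c == ID_COLUMN:
            continue
        (num if pd.api.types.is_numeric_dtype(table[c]) else cat).append(c)
    return num, cat


def build_feature_matrix(table: pd.DataFrame, standardize: bool = True) -> FeatureMatrix:
    """Impute, dummy-encode and (optionally) z-standardize a phenotype table.

    Parameters
    ----------
    table : DataFrame with a ``sample_id`` column, numeric item columns and
        string/categorical columns; missing values allowed anywhere.
    standardize : z-score every column after encoding (default). The
        downstream autoencoder is scale-sensitive, hence the default.
    """
    if ID_COLUMN not in table.columns:
        raise ValueError(f"phenotype table must have a {ID_COLUMN!r} column")
    if table[ID_COLUMN].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    num_cols, cat_cols = split_columns(table)
    blocks, names, prov = [], [], []
    if num_cols:
        numeric = mean_impute(table[num_cols].astype(float))
        for c in numeric.columns:
            blocks.append(numeric[c].to_numpy(float))
            names.append(c)
            prov.append((c, None))
    for c in cat_cols:
        col = table[c].astype("object").where(table[c].notna(), "missing")
        levels = sorted(map(str, col.unique()))
        for lv in levels:
            blocks.append((col.astype(str) == lv).to_numpy(float))
            names.append(f"{c}={lv}")
            prov.append((c, lv))
    if not blocks:
        raise ValueError("no usable phenotype columns")
    X = np.column_stack(blocks)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping constant column(s): {[n for n, k in zip(names, keep) if not k]}"
        )
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    prov = [p for p, k in zip(prov, keep) if k]
    if X.shape[1] == 0:
        raise ValueError("all columns constant; nothing to cluster on")
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    return FeatureMatrix(list(table[ID_COLUMN]), X, names, prov)
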