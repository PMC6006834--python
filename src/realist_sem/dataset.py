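"""Clustered rectangular data for covariance-structure analysis.

Rows are individuals; a cluster column identifies the GP practice (or any
grouping unit) each row belongs to.  Ordinal Likert items are carried as
numeric codes and modelled as continuous; a per-variable flag records which
columns are ordinal so downstream code can refuse declared-categorical use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClusteredDataset", "sample_covariance"]


@dataclass
class ClusteredDataset:
    """A pandas DataFrame plus cluster labels and scale metadata.

    Parameters
    ----------
    frame : DataFrame with one row per individual, numeric analysis columns.
    cluster_column : name of the column holding opaque cluster labels.
    ordinal : set of column names that are Likert codes treated as continuous.
    """

    frame: pd.DataFrame
    cluster_column: str
    ordinal: set[str] = field(default_factory=set)
    #: columns that are truly categorical (labels, not ordered codes); the
    #: engine refuses to model these — recode ordered scales as numeric and
    #: flag them in `ordinal` instead (the ordinal-as-continuous convention)
    categorical: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.cluster_column not in self.frame.columns:
            raise ValueError(
                f"cluster column {self.cluster_column!r} not present in data"
            )

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_clusters(self) -> int:
        return self.frame[self.cluster_column].nunique()

    def cluster_labels(self) -> np.ndarray:
        return self.frame[self.cluster_column].to_numpy()

    def complete_cases(self, variables: list[str]) -> tuple["ClusteredDataset", int]:
        """Listwise deletion on `variables`; returns (subset, n_dropped)."""
        missing = [v for v in variables if v not in self.frame.columns]
        if missing:
            raise KeyError(f"variables not present in data: {missing}")
        sub = self.frame.dropna(subset=variables)
        return (
            ClusteredDataset(sub.reset_index(drop=True), self.cluster_column, self.ordinal),
            len(self.frame) - len(sub),
        )

    def matrix(self, variables: list[str]) -> np.ndarray:
        """n x p numeric matrix in the requested column order."""
        missing = [v for v in variables if v not in self.frame.columns]
        if missing:
            raise KeyError(f"variables not present in data: {missing}")
        return self.frame[variables].to_numpy(dtype=float)


def sample_covariance(data: ClusteredDataset, variables: list[str]) -> np.ndarray:
    """Biased (divisor n) sample covariance of the requested variables.

    The divisor-n convention pairs with the fit function and the
    T = (n-1) * F chi-square convention used by the fit indices.
    Raises on constant columns, naming the offending variable.
    """
    x = data.matrix(variables)
    n = x.shape[0]
    if n < 2:
        raise ValueError("at least two complete rows are required")
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / n
    zero = [v for v, var in zip(variables, np.diag(s)) if var <= 0.0]
    if zero:
        raise ValueError(f"zero-variance variable(s): {zero}")
    return s
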