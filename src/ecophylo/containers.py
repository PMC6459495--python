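"""Shared in-memory containers and validation helpers.

Community matrices are plain :class:`pandas.DataFrame` objects (sampling
units in rows, species in columns, non-negative integer occurrence counts).
Distance matrices get a thin dedicated wrapper because several stages pass
them around with invariants (symmetry, zero diagonal) that a bare DataFrame
does not enforce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "validate_community_matrix"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal.

    Parameters
    ----------
    labels : sequence of str
        Object labels, in row/column order.
    values : ndarray of shape (n, n)
        Distances. Must be symmetric to 1e-12, non-negative, zero diagonal.
    """

    labels: tuple
    values: np.ndarray = field(repr=False)

    def __init__(self, labels: Sequence[str], values):
        values = np.asarray(values, dtype=float)
        labels = tuple(labels)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
            raise ValueError("distance matrix is not symmetric")
        if np.any(values < 0):
            raise ValueError("negative distances")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.labels), columns=list(self.labels))

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy restricted/reordered to ``labels``."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def rescaled(self) -> "DistanceMatrix":
        """Rescale to [0, 1] by dividing by the matrix maximum."""
        m = self.values.max()
        if m == 0:
            raise ValueError("cannot rescale an all-zero distance matrix")
        return DistanceMatrix(self.labels, self.values / m)

    @property
    def max(self) -> float:
        return float(self.values.max())


def validate_community_matrix(W: pd.DataFrame, allow_zero_rows: bool = True) -> pd.DataFrame:
    """Check a community matrix: unique labels, non-negative integer counts."""
    if not isinstance(W, pd.DataFrame):
        raise TypeError("community matrix must be a pandas DataFrame")
    if W.shape[0] == 0 or W.shape[1] == 0:
        raise ValueError("community matrix is empty")
    if W.columns.duplicated().any():
        raise ValueError("duplicate species labels")
    if W.index.duplicated().any():
        raise ValueError("duplicate unit labels")
    vals = W.to_numpy()
    if np.any(vals < 0):
        raise ValueError("negative occurrence counts")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("occurrence counts must be integers")
    if not allow_zero_rows and np.any(vals.sum(axis=1) == 0):
        bad = W.index[vals.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero sampling units: {bad}")
    return W
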