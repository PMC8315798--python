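"""Parcellated structural connectome container.

The long-range coupling substrate is a nonnegative N x N weight matrix
over cortical parcels. The diagonal is zeroed (local recurrence is modeled
explicitly) and each row is normalized to unit sum, so that total
long-range input to every node is balanced. An optional symmetric
inter-parcel distance matrix supports variogram-based surrogate maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StructuralConnectome"]


@dataclass
class StructuralConnectome:
    """Row-normalized structural connectivity over labeled parcels.

    Construct via :meth:`from_weights` to apply diagonal zeroing and row
    normalization once, at load time; the constructor itself only
    validates, so normalization is never silently re-applied.
    """

    C: np.ndarray
    labels: list[str]
    D: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be a square matrix")
        n = self.C.shape[0]
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != n:
            raise ValueError("labels length must match C")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if np.any(self.C < 0):
            raise ValueError("C must be nonnegative")
        if np.any(np.diag(self.C) != 0):
            raise ValueError("diagonal of C must be zero")
        rowsums = self.C.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError(
                "rows of C must sum to 1; build via StructuralConnectome.from_weights"
            )
        if self.D is not None:
            self.D = np.asarray(self.D, dtype=float)
            if self.D.shape != self.C.shape:
                raise ValueError("D must match C in shape")
            if not np.allclose(self.D, self.D.T):
                raise ValueError("D must be symmetric")
            if np.any(np.diag(self.D) != 0):
                raise ValueError("D must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]

    @classmethod
    def from_weights(
        cls,
        weights: np.ndarray,
        labels: list[str] | None = None,
        D: np.ndarray | None = None,
    ) -> "StructuralConnectome":
        """Zero the diagonal and row-normalize raw nonnegative weights."""
        W = np.array(weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        np.fill_diagonal(W, 0.0)
        rowsums = W.sum(axis=1)
        if np.any(rowsums == 0):
            raise ValueError("every node needs at least one nonzero connection")
        W = W / rowsums[:, None]
        if labels is None:
            labels = [f"parcel{i:03d}" for i in range(W.shape[0])]
        return cls(C=W, labels=list(labels), D=D)
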