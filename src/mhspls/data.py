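"""Paired two-view data container.

A :class:`TwoViewDataset` holds two numeric matrices with matched rows
(samples): a high-dimensional view ``X`` (n x p, e.g. voxelwise grey-matter
probability values) and a lower-dimensional view ``Y`` (n x q, e.g. per-item
clinical scores). All model code in this package operates on this container
or on plain arrays sliced from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TwoViewDataset"]


@dataclass
class TwoViewDataset:
    """Two sample-by-feature matrices with matched rows.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        First view (e.g. imaging features).
    Y : ndarray, shape (n, q)
        Second view (e.g. clinical items).
    x_names, y_names : sequence of str, optional
        Feature labels per view; auto-generated when omitted.
    sample_ids : sequence of str, optional
        Row identifiers shared by both views.
    x_meta : dict, optional
        Extra metadata for the X view (used for NIfTI-backed data: mask
        shape, affine and the linear voxel indices of the columns).
    """

    X: np.ndarray
    Y: np.ndarray
    x_names: list[str] | None = None
    y_names: list[str] | None = None
    sample_ids: list[str] | None = None
    x_meta: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D matrices")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X and Y must have the same number of rows "
                f"(got {self.X.shape[0]} and {self.Y.shape[0]})"
            )
        if self.n < 2:
            raise ValueError("need at least 2 samples")
        if self.p < 1 or self.q < 1:
            raise ValueError("each view needs at least one feature")
        if not np.isfinite(self.X).all() or not np.isfinite(self.Y).all():
            raise ValueError("X and Y must not contain NaN or infinite entries")
        if self.x_names is None:
            self.x_names = [f"x{j}" for j in range(self.p)]
        if self.y_names is None:
            self.y_names = [f"y{j}" for j in range(self.q)]
        self.x_names = [str(s) for s in self.x_names]
        self.y_names = [str(s) for s in self.y_names]
        if len(self.x_names) != self.p:
            raise ValueError("x_names length does not match the number of X columns")
        if len(self.y_names) != self.q:
            raise ValueError("y_names length does not match the number of Y columns")
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != self.n:
                raise ValueError("sample_ids length does not match the number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    def subset(self, rows: np.ndarray) -> "TwoViewDataset":
        """Return a new dataset restricted to the given row indices."""
        rows = np.asarray(rows)
        ids = None if self.sample_ids is None else [self.sample_ids[i] for i in rows]
        return replace(self, X=self.X[rows], Y=self.Y[rows], sample_ids=ids)
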