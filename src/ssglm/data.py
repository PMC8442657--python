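"""The (y, X, family) bundle consumed by every stage.

Predictor indices are 1-based throughout the public API (index 0 is reserved
for the intercept, matching the coefficient-vector layout); column ``j`` of
``X`` therefore holds predictor ``j``'s values at ``X[:, j-1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import Family, get_family

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """Design matrix, response and family tag.

    Parameters
    ----------
    X : (n, p) numeric design matrix, one row per sample, no intercept column.
    y : (n,) response; values must be admissible for ``family``.
    family : "gaussian" | "binomial" | "poisson" (or a Family instance).
    names : optional predictor names (length p); defaults to x1..xp.
    """

    X: np.ndarray
    y: np.ndarray
    family: Family
    names: list[str] = field(default=None)

    def __post_init__(self):
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.family = get_family(self.family)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.size} entries"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        self.family.check_response(self.y)
        if self.names is None:
            self.names = [f"x{j}" for j in range(1, self.p + 1)]
        elif len(self.names) != self.p:
            raise ValueError("names length does not match number of predictors")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "Dataset":
        """Row subset (used for the two halves of a split)."""
        return Dataset(self.X[rows], self.y[rows], self.family, self.names)

    @classmethod
    def from_csv(cls, x_path, y_path, family) -> "Dataset":
        """Read the design from a delimited file with a header row of
        predictor names, and the response from a one-column file."""
        Xdf = pd.read_csv(x_path, sep=None, engine="python")
        ydf = pd.read_csv(y_path, sep=None, engine="python")
        return cls(
            Xdf.to_numpy(dtype=float),
            ydf.iloc[:, 0].to_numpy(dtype=float),
            family,
            names=[str(c) for c in Xdf.columns],
        )

    def to_csv(self, x_path, y_path) -> None:
        pd.DataFrame(self.X, columns=self.names).to_csv(x_path, index=False)
        pd.DataFrame({"y": self.y}).to_csv(y_path, index=False)
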