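"""Gini-index covariance and correlation matrices for binary variables.

For categorical data the covariance between variables ``x_i`` and ``x_j`` is
defined through pairwise dissimilarities over all ordered subject pairs,

    Q_ij = 1/(2 m^2) * sum_a sum_b (x_ia - x_ib) L (x_ja - x_jb),

with an orthogonal transformation ``L`` that is the identity for the binary
(0/1) case handled here.  On the diagonal this is Gini's variance
("likeability"), which for a binary variable equals p(1-p).  Expanding the
double sum shows the identity-``L`` form equals the ordinary mean-centered
product-moment covariance with divisor ``m`` (not ``m - 1``); the
implementation uses that closed form, and the test-suite keeps the explicit
double sum as an independent oracle.

Missing values are handled by pairwise-available-case analysis: each matrix
entry is computed over the subjects complete for that *pair* of variables,
with the pair's own complete-case count ``m`` and means used in all terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import EXPOSURE_X, CohortTable

__all__ = [
    "AssociationMatrices",
    "UndefinedCovarianceError",
    "gini_pair_covariance",
    "gini_covariance_matrix",
    "gini_correlation_matrix",
]


class UndefinedCovarianceError(ValueError):
    """Raised when a pair of variables has fewer than 2 complete cases."""


@dataclass
class AssociationMatrices:
    """Gini covariance/correlation matrices with pairwise-n bookkeeping.

    ``V`` and ``R`` are ``(p+q) x (p+q)`` with X-set variables first;
    ``pairwise_n[i, j]`` counts the subjects complete for variables i and j.
    ``zero_variance`` lists constant variables whose off-diagonal correlation
    entries were set to 0.  ``repair_log`` collects any positive-semidefinite
    adjustments applied downstream (the CCA solver appends to it).
    """

    variable_names: list[str]
    set_assignment: dict[str, str]
    V: np.ndarray
    pairwise_n: np.ndarray
    R: np.ndarray | None = None
    L: str = "identity"
    zero_variance: list[str] = field(default_factory=list)
    repair_log: list[str] = field(default_factory=list)

    @property
    def x_names(self) -> list[str]:
        return [v for v in self.variable_names if self.set_assignment[v] == EXPOSURE_X]

    @property
    def y_names(self) -> list[str]:
        return [v for v in self.variable_names if self.set_assignment[v] != EXPOSURE_X]

    @property
    def p(self) -> int:
        return len(self.x_names)

    @property
    def q(self) -> int:
        return len(self.y_names)

    def _block(self, M: np.ndarray, rows: str, cols: str) -> np.ndarray:
        p = self.p
        sl = {"x": slice(0, p), "y": slice(p, None)}
        return M[sl[rows], sl[cols]]

    @property
    def S_xx(self) -> np.ndarray:
        return self._block(self.V, "x", "x")

    @property
    def S_yy(self) -> np.ndarray:
        return self._block(self.V, "y", "y")

    @property
    def S_xy(self) -> np.ndarray:
        return self._block(self.V, "x", "y")

    def matrix_frame(self, which: str = "V") -> pd.DataFrame:
        M = {"V": self.V, "R": self.R, "pairwise_n": self.pairwise_n}[which]
        if M is None:
            raise ValueError(f"matrix {which!r} has not been computed")
        return pd.DataFrame(M, index=self.variable_names, columns=self.variable_names)


def gini_pair_covariance(x: np.ndarray, y: np.ndarray, L: str | None = None) -> float:
    """Gini covariance of two binary vectors over their complete cases.

    Equals ``(1/(2 m^2)) * sum_a sum_b (x_a - x_b)(y_a - y_b)`` over the
    ``m`` subjects where both entries are observed; for ``x is y`` this is
    the Gini variance p(1-p).
    """
    _check_L(L)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    m = int(keep.sum())
    if m < 2:
        raise UndefinedCovarianceError(
            f"only {m} complete case(s); at least 2 are required"
        )
    xs, ys = x[keep], y[keep]
    # closed form of the double sum: (1/m) sum x*y - mean(x) mean(y)
    return float(xs @ ys / m - xs.mean() * ys.mean())


def _check_L(L: str | None) -> None:
    if L not in (None, "identity", 1, 1.0):
        raise NotImplementedError(
            "only the identity transformation L is supported for binary data"
        )


def gini_covariance_matrix(table: CohortTable, L: str | None = None) -> AssociationMatrices:
    """Entrywise Gini covariance matrix with pairwise-available-case deletion.

    Vectorized over all pairs: with ``A`` the data matrix with missing cells
    zeroed and ``M`` the 0/1 presence mask, ``M'M`` counts complete pairs,
    ``A'A`` accumulates cross-products and ``A'M`` the per-pair sums, from
    which each entry's divisor-``m`` covariance follows.
    """
    _check_L(L)
    if table.n < 2:
        raise UndefinedCovarianceError("need at least 2 subjects")
    order = table.x_names + table.y_names
    idx = [table.variable_names.index(v) for v in order]
    data = table.values[:, idx]

    V, m = _pairwise_cov(data)
    if np.any(m < 2):
        i, j = np.argwhere(m < 2)[0]
        raise UndefinedCovarianceError(
            f"pair ({order[i]!r}, {order[j]!r}) has {int(m[i, j])} complete case(s)"
        )
    zero_var = [order[i] for i in range(len(order)) if V[i, i] <= 0.0]
    if zero_var:
        warnings.warn(
            f"zero-variance variables flagged: {zero_var}; their correlations are set to 0",
            stacklevel=2,
        )
    return AssociationMatrices(
        variable_names=order,
        set_assignment={v: table.set_assignment[v] for v in order},
        V=V,
        pairwise_n=m,
        zero_variance=zero_var,
    )


def _pairwise_cov(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete covariance (divisor m) and complete-pair counts."""
    M = np.isfinite(data).astype(float)
    A = np.where(M > 0, data, 0.0)
    m = M.T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        cross = (A.T @ A) / m
        sum_i = (A.T @ M) / m  # mean of variable i over pair-complete cases
        V = cross - sum_i * sum_i.T
    V = (V + V.T) / 2.0  # enforce exact symmetry against float noise
    return V, m.astype(int)


def gini_correlation_matrix(assoc: AssociationMatrices) -> AssociationMatrices:
    """Fill ``R_ij = V_ij / sqrt(V_ii V_jj)``; diagonal set exactly to 1.

    Zero-variance variables get off-diagonal entries of 0 (they carry no
    association information) and a diagonal of 1 for bookkeeping.
    """
    V = assoc.V
    d = np.diag(V).copy()
    ok = d > 0
    scale = np.ones_like(d)
    scale[ok] = 1.0 / np.sqrt(d[ok])
    R = V * np.outer(scale, scale)
    R[~ok, :] = 0.0
    R[:, ~ok] = 0.0
    np.fill_diagonal(R, 1.0)
    assoc.R = R
    return assoc
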