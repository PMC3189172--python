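"""Canonical correlation analysis from Gini covariance blocks.

Given within-set covariance blocks ``S_xx`` (p x p), ``S_yy`` (q x q) and the
between-set block ``S_xy`` (p x q), the canonical weights maximize

    corr(a'x, b'y) = a' S_xy b / sqrt(a' S_xx a * b' S_yy b)

and are obtained from the two eigenvalue problems

    (S_xx^-1 S_xy S_yy^-1 S_yx - lambda I) a = 0
    (S_yy^-1 S_yx S_xx^-1 S_xy - lambda I) b = 0,

whose shared nonzero eigenvalues ``lambda_k = rho_k^2`` are the squared
canonical correlations.  Pairwise-deleted covariance matrices need not be
positive semidefinite, so each within-set block is repaired by symmetric
eigenvalue clipping (floor ``1e-8 * trace / dim``), optionally plus a ridge,
before inversion; every adjustment is appended to the solution's
``repair_log``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .gini import AssociationMatrices

__all__ = [
    "CanonicalSolution",
    "SingularBlockError",
    "solve_cca",
    "canonical_scores",
    "structural_coefficients",
    "redundancy",
    "percent_of_variation",
    "cross_loading_from_identity",
    "sequential_wilks",
]

_PSD_FLOOR_SCALE = 1e-8
_IMAG_TOL = 1e-8


class SingularBlockError(np.linalg.LinAlgError):
    """A within-set covariance block is singular even after PSD repair."""


@dataclass
class CanonicalSolution:
    """Canonical correlations, weights and derived structural quantities.

    All per-variate arrays are ordered by descending canonical correlation;
    weights satisfy ``a_k' S_xx a_k = b_k' S_yy b_k = 1`` so the canonical
    variates have unit variance.
    """

    x_names: list[str]
    y_names: list[str]
    rho: np.ndarray          # (K,) canonical correlations, descending
    lam: np.ndarray          # (K,) squared canonical correlations
    A: np.ndarray            # (p, K) X-side weight vectors
    B: np.ndarray            # (q, K) Y-side weight vectors
    loadings_x: np.ndarray   # (p, K) corr(x_i, U_k)
    loadings_y: np.ndarray   # (q, K) corr(y_j, V_k)
    cross_x: np.ndarray      # (p, K) corr(x_i, V_k) = rho_k * loadings_x
    cross_y: np.ndarray      # (q, K) corr(y_j, U_k)
    redundancy_y_given_x: np.ndarray  # (K,)
    redundancy_x_given_y: np.ndarray  # (K,)
    repair_log: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.rho.size

    @property
    def p(self) -> int:
        return len(self.x_names)

    @property
    def q(self) -> int:
        return len(self.y_names)

    def loadings_frame(self) -> pd.DataFrame:
        """Long-format table of loadings and cross-loadings per variate."""
        rows = []
        for names, side, load, cross in (
            (self.x_names, "exposure_X", self.loadings_x, self.cross_x),
            (self.y_names, "outcome_Y", self.loadings_y, self.cross_y),
        ):
            for i, v in enumerate(names):
                for k in range(self.K):
                    rows.append(
                        {
                            "variable": v,
                            "set": side,
                            "variate": k + 1,
                            "loading": load[i, k],
                            "cross_loading": cross[i, k],
                            "pct_of_variation": percent_of_variation(load[i, k], digits=2),
                        }
                    )
        return pd.DataFrame(rows)


def percent_of_variation(loading: float, digits: int | None = 0) -> float:
    """Squared loading expressed as a percent of the variate's variation.

    A variable with loading 0.94 contributes ``round(100 * 0.94**2) = 88``
    percent of its canonical variate's variation.  ``digits=None`` returns
    the unrounded percent.
    """
    pct = 100.0 * float(loading) ** 2
    return pct if digits is None else round(pct, digits or None)


def cross_loading_from_identity(rho: float, loading: float) -> float:
    """Cross-loading implied by the identity corr(x_i, V_k) = rho_k * loading."""
    return float(rho) * float(loading)


def sequential_wilks(lam: np.ndarray) -> np.ndarray:
    """Sequential Wilks statistics ``Lambda_k = prod_{j>=k} (1 - lambda_j)``.

    Small values indicate association carried by variate ``k`` and beyond.
    """
    lam = np.asarray(lam, dtype=float)
    return np.cumprod((1.0 - lam)[::-1])[::-1]


def canonical_lambdas(
    Sxx_inv: np.ndarray, Syy_inv: np.ndarray, Sxy: np.ndarray, side: str = "auto"
) -> np.ndarray:
    """Squared canonical correlations from pre-inverted within-set blocks.

    ``side`` picks which of the two eigenvalue problems is solved ("x" for
    the p x p problem, "y" for the q x q one, "auto" for the smaller);
    eigenvalues are returned clipped into [0, 1] and sorted descending, top
    min(p, q).  Used by the permutation engine, where the within-set blocks
    (invariant under row permutation of one set) are factored once.
    """
    p, q = Sxy.shape
    K = min(p, q)
    if side == "auto":
        side = "x" if p <= q else "y"
    if side == "x":
        M = Sxx_inv @ Sxy @ Syy_inv @ Sxy.T
    elif side == "y":
        M = Syy_inv @ Sxy.T @ Sxx_inv @ Sxy
    else:
        raise ValueError("side must be 'x', 'y' or 'auto'")
    lam = np.linalg.eigvals(M)
    if np.abs(lam.imag).max(initial=0.0) > _IMAG_TOL * (1.0 + np.abs(lam.real).max(initial=0.0)):
        raise np.linalg.LinAlgError("complex eigenvalue residuals beyond tolerance")
    lam = np.clip(np.sort(lam.real)[::-1][:K], 0.0, 1.0)
    return lam


def _clip_psd(S: np.ndarray, label: str, ridge: float, log: list[str]) -> np.ndarray:
    """Symmetric-eigenvalue clipping to a trace-scaled floor, plus ridge."""
    S = (S + S.T) / 2.0
    if ridge > 0.0:
        S = S + ridge * np.eye(S.shape[0])
        log.append(f"{label}: ridge {ridge:g} added to diagonal")
    w, Q = np.linalg.eigh(S)
    floor = _PSD_FLOOR_SCALE * max(np.trace(S), 0.0) / S.shape[0]
    floor = max(floor, _PSD_FLOOR_SCALE)
    if w.min() < floor:
        n_clip = int((w < floor).sum())
        log.append(
            f"{label}: clipped {n_clip} eigenvalue(s) below {floor:.3e} "
            f"(min was {w.min():.3e})"
        )
        w = np.maximum(w, floor)
        S = (Q * w) @ Q.T
        S = (S + S.T) / 2.0
    return S


def _real_eig(M: np.ndarray, label: str) -> tuple[np.ndarray, np.ndarray]:
    w, U = np.linalg.eig(M)
    if np.abs(w.imag).max(initial=0.0) > _IMAG_TOL * (1.0 + np.abs(w.real).max(initial=0.0)):
        raise np.linalg.LinAlgError(
            f"{label}: complex eigenvalue residuals beyond tolerance"
        )
    return w.real, U.real


def solve_cca(
    assoc: AssociationMatrices,
    ridge: float = 0.0,
    drop_zero_variance: bool = True,
) -> CanonicalSolution:
    """Solve the canonical correlation problem from covariance blocks.

    Both eigenvalue problems are solved; their shared eigenvalues are the
    squared canonical correlations.  Zero-variance variables flagged by the
    association step are dropped (with a repair-log entry) rather than making
    the blocks singular.  Each variate's sign is fixed so the X-side variable
    with the largest |loading| loads positively.
    """
    repair_log = list(assoc.repair_log)
    x_names, y_names = assoc.x_names, assoc.y_names
    if drop_zero_variance and assoc.zero_variance:
        dropped = [v for v in assoc.zero_variance]
        repair_log.append(f"dropped zero-variance variables: {dropped}")
        x_names = [v for v in x_names if v not in assoc.zero_variance]
        y_names = [v for v in y_names if v not in assoc.zero_variance]
    if not x_names or not y_names:
        raise SingularBlockError("a set has no variables with positive variance")

    names = assoc.variable_names
    ix = [names.index(v) for v in x_names]
    iy = [names.index(v) for v in y_names]
    Sxx = assoc.V[np.ix_(ix, ix)]
    Syy = assoc.V[np.ix_(iy, iy)]
    Sxy = assoc.V[np.ix_(ix, iy)]

    Sxx = _clip_psd(Sxx, "S_xx", ridge, repair_log)
    Syy = _clip_psd(Syy, "S_yy", ridge, repair_log)
    try:
        Sxx_inv = np.linalg.inv(Sxx)
        Syy_inv = np.linalg.inv(Syy)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - repair makes this rare
        raise SingularBlockError(
            "within-set covariance block singular after repair; "
            "prune collinear or near-constant variables"
        ) from exc

    p, q = len(ix), len(iy)
    K = min(p, q)
    Mx = Sxx_inv @ Sxy @ Syy_inv @ Sxy.T  # p x p problem for a
    My = Syy_inv @ Sxy.T @ Sxx_inv @ Sxy  # q x q problem for b
    lam_x, Ux = _real_eig(Mx, "X-side eigenproblem")
    lam_y, _ = _real_eig(My, "Y-side eigenproblem")

    order = np.argsort(-lam_x, kind="stable")[:K]
    lam = lam_x[order]
    lam_y_top = np.sort(lam_y)[::-1][:K]
    if np.max(np.abs(lam - lam_y_top)) > 1e-8 * (1.0 + np.abs(lam).max(initial=0.0)):
        raise np.linalg.LinAlgError(
            "X-side and Y-side eigenproblems disagree beyond tolerance"
        )
    clipped = np.clip(lam, 0.0, 1.0)
    if np.max(np.abs(clipped - lam)) > 1e-8:
        repair_log.append(
            f"eigenvalues clipped into [0, 1] (max deviation {np.max(np.abs(clipped - lam)):.3e})"
        )
    lam = clipped
    rho = np.sqrt(lam)

    A = np.empty((p, K))
    B = np.empty((q, K))
    for k, j in enumerate(order):
        a = Ux[:, j]
        na = float(a @ Sxx @ a)
        if na <= 0:
            raise SingularBlockError("degenerate X-side weight vector")
        a = a / np.sqrt(na)
        b = Syy_inv @ Sxy.T @ a
        nb = float(b @ Syy @ b)
        if nb > 0:
            b = b / np.sqrt(nb)
        if a @ Sxy @ b < 0:
            b = -b
        A[:, k], B[:, k] = a, b

    dx = np.sqrt(np.diag(Sxx))
    dy = np.sqrt(np.diag(Syy))
    loadings_x = (Sxx @ A) / dx[:, None]
    loadings_y = (Syy @ B) / dy[:, None]
    # sign convention: dominant X variable loads positively on each variate
    for k in range(K):
        i_max = int(np.argmax(np.abs(loadings_x[:, k])))
        if loadings_x[i_max, k] < 0:
            A[:, k] *= -1
            B[:, k] *= -1
            loadings_x[:, k] *= -1
            loadings_y[:, k] *= -1
    cross_x = (Sxy @ B) / dx[:, None]
    cross_y = (Sxy.T @ A) / dy[:, None]

    red_y = (loadings_y**2).mean(axis=0) * lam
    red_x = (loadings_x**2).mean(axis=0) * lam

    return CanonicalSolution(
        x_names=list(x_names),
        y_names=list(y_names),
        rho=rho,
        lam=lam,
        A=A,
        B=B,
        loadings_x=loadings_x,
        loadings_y=loadings_y,
        cross_x=cross_x,
        cross_y=cross_y,
        redundancy_y_given_x=red_y,
        redundancy_x_given_y=red_x,
        repair_log=repair_log,
    )


def canonical_scores(
    table: CohortTable, solution: CanonicalSolution
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject canonical variate scores ``U = Xc A`` and ``V = Yc B``.

    Columns are centered at their observed prevalence means.  A subject
    missing any variable used by a side gets NaN scores on that side.
    """
    def side_scores(names: list[str], W: np.ndarray) -> np.ndarray:
        cols = np.column_stack([table.column(v) for v in names])
        centered = cols - np.nanmean(cols, axis=0)
        scores = np.where(np.isfinite(centered), centered, 0.0) @ W
        scores[~np.all(np.isfinite(cols), axis=1)] = np.nan
        return scores

    return side_scores(solution.x_names, solution.A), side_scores(solution.y_names, solution.B)


def structural_coefficients(
    assoc: AssociationMatrices, solution: CanonicalSolution
) -> pd.DataFrame:
    """Loadings, cross-loadings and percent-of-variation per variable/variate.

    Loadings are correlations between each original variable and its own
    set's canonical variate; cross-loadings use the opposite set's variate
    and obey ``cross = rho_k * loading``.
    """
    return solution.loadings_frame()


def redundancy(
    assoc: AssociationMatrices, solution: CanonicalSolution
) -> pd.DataFrame:
    """Per-variate redundancy: mean squared loading times lambda_k.

    ``redundancy_y_given_x[k]`` is the share of total Y-set variance
    explained by the k-th X-side canonical variate (and symmetrically).
    """
    return pd.DataFrame(
        {
            "variate": np.arange(1, solution.K + 1),
            "rho": solution.rho,
            "lambda": solution.lam,
            "redundancy_y_given_x": solution.redundancy_y_given_x,
            "redundancy_x_given_y": solution.redundancy_x_given_y,
        }
    )
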