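"""Permutation significance tests and resampling standard errors for CCA.

Binary indicator data violate the multivariate normality behind parametric
canonical-correlation tests, so significance is assessed nonparametrically:
whole Y-set rows (missingness pattern included) are permuted against the
X-set rows, breaking between-set association while preserving each set's
internal dependence, and the full pipeline (pairwise Gini covariance ->
CCA eigenproblem) is re-run per permutation.

Variates are tested sequentially with the Wilks-type statistic
``Lambda_k = prod_{j>=k} (1 - lambda_j)``; the p-value for variate k is the
add-one permutation fraction ``(#{Lambda_k^perm <= Lambda_k^obs} + 1) /
(n_perm + 1)``, so it is never exactly zero.

Standard errors of the canonical correlations default to a subject
bootstrap; the spread of the permutation null distribution is available as
an alternative (``method="permutation"``) but describes the null, not the
estimator's sampling variability.

A key exactness shortcut: permuting the Y rows leaves the within-set blocks
``S_xx`` and ``S_yy`` (and their pairwise counts) unchanged — the same rows
are present, only re-paired — so only the between-set block ``S_xy`` is
recomputed per permutation, against pre-factored within-set inverses.  The
test-suite checks this equals a from-scratch re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cca import CanonicalSolution, _clip_psd, canonical_lambdas, sequential_wilks, solve_cca
from .cohort import CohortTable
from .gini import gini_covariance_matrix

__all__ = ["InferenceResult", "PermutationFailureError", "permutation_test", "resample_se"]


class PermutationFailureError(RuntimeError):
    """More than the tolerated share of permutation replicates failed."""


@dataclass
class InferenceResult:
    """Per-variate permutation p-values with reproducibility metadata."""

    rho: np.ndarray
    p_values: np.ndarray
    n_perm: int
    seed: int
    statistic: str = "sequential_wilks"
    n_failed: int = 0
    null_rho_sd: np.ndarray | None = None
    null_quantiles: pd.DataFrame | None = None
    standard_errors: np.ndarray | None = None
    se_method: str | None = None

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "variate": np.arange(1, self.rho.size + 1),
                "rho": self.rho,
                "p_value": self.p_values,
            }
        )
        if self.standard_errors is not None:
            out["se"] = self.standard_errors
        out["n_perm"] = self.n_perm
        out["seed"] = self.seed
        out["statistic"] = self.statistic
        return out


def _blocks_for_permutation(table: CohortTable, ridge: float):
    """Precompute everything invariant under permutation of the Y rows."""
    assoc = gini_covariance_matrix(table)
    keep_x = [v for v in assoc.x_names if v not in assoc.zero_variance]
    keep_y = [v for v in assoc.y_names if v not in assoc.zero_variance]
    names = assoc.variable_names
    ix = [names.index(v) for v in keep_x]
    iy = [names.index(v) for v in keep_y]
    log: list[str] = []
    Sxx = _clip_psd(assoc.V[np.ix_(ix, ix)], "S_xx", ridge, log)
    Syy = _clip_psd(assoc.V[np.ix_(iy, iy)], "S_yy", ridge, log)
    Sxx_inv = np.linalg.inv(Sxx)
    Syy_inv = np.linalg.inv(Syy)

    order = table.x_names + table.y_names
    idx = [table.variable_names.index(v) for v in order]
    data = table.values[:, idx]
    Xdat = data[:, [order.index(v) for v in keep_x]]
    Ydat = data[:, [order.index(v) for v in keep_y]]
    return assoc, Sxx_inv, Syy_inv, Xdat, Ydat


def _cross_block(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise-complete divisor-m cross-covariance between two data blocks."""
    Mx = np.isfinite(X).astype(float)
    My = np.isfinite(Y).astype(float)
    Ax = np.where(Mx > 0, X, 0.0)
    Ay = np.where(My > 0, Y, 0.0)
    m = Mx.T @ My
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Ax.T @ Ay) / m - ((Ax.T @ My) / m) * ((Mx.T @ Ay) / m)


def permutation_test(
    table: CohortTable,
    n_perm: int = 10_000,
    seed: int = 0,
    ridge: float = 0.0,
    max_failure_rate: float = 0.05,
) -> InferenceResult:
    """Sequential permutation test of the canonical variates.

    Requires ``n_perm >= 99``.  Results are reproducible bit-for-bit given
    ``(seed, n_perm)``.  Permutation replicates whose covariance or
    eigen-solve fails are dropped and counted; more than
    ``max_failure_rate`` failures raise :class:`PermutationFailureError`.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    solution = solve_cca(gini_covariance_matrix(table), ridge=ridge)
    _, Sxx_inv, Syy_inv, Xdat, Ydat = _blocks_for_permutation(table, ridge)
    K = solution.K
    obs_wilks = sequential_wilks(solution.lam)

    rng = np.random.default_rng(seed)
    n = table.n
    exceed = np.zeros(K, dtype=int)
    null_rho = np.empty((n_perm, K))
    n_failed = 0
    kept = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        try:
            Sxy = _cross_block(Xdat, Ydat[perm])
            if not np.all(np.isfinite(Sxy)):
                raise np.linalg.LinAlgError("pair with <2 complete cases")
            lam = canonical_lambdas(Sxx_inv, Syy_inv, Sxy)
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
        w = sequential_wilks(lam)
        exceed += w <= obs_wilks
        null_rho[kept] = np.sqrt(lam)
        kept += 1
    if n_failed > max_failure_rate * n_perm:
        raise PermutationFailureError(
            f"{n_failed}/{n_perm} permutation replicates failed to solve"
        )
    null_rho = null_rho[:kept]
    p_values = (exceed + 1) / (kept + 1)
    qgrid = [0.025, 0.25, 0.5, 0.75, 0.975]
    null_quantiles = pd.DataFrame(
        np.quantile(null_rho, qgrid, axis=0).T,
        columns=[f"q{q}" for q in qgrid],
        index=pd.RangeIndex(1, K + 1, name="variate"),
    )
    return InferenceResult(
        rho=solution.rho,
        p_values=p_values,
        n_perm=kept,
        seed=seed,
        n_failed=n_failed,
        null_rho_sd=null_rho.std(axis=0, ddof=1),
        null_quantiles=null_quantiles,
    )


def resample_se(
    table: CohortTable,
    n_resample: int = 1000,
    seed: int = 0,
    method: str = "bootstrap",
    ridge: float = 0.0,
    max_retries: int = 10,
) -> np.ndarray:
    """Standard errors of the canonical correlations per variate.

    ``method="bootstrap"`` (default) resamples subjects with replacement and
    re-runs the full pipeline; the SE is the standard deviation of each
    ``rho_k`` across resamples.  ``method="permutation"`` instead reports
    the spread of the permutation null distribution — a null-scale summary,
    not a sampling SE.  Degenerate resamples (a zero-variance column, or a
    pair with too few complete cases) are re-drawn up to ``max_retries``
    times.
    """
    if method == "permutation":
        res = permutation_test(table, n_perm=max(n_resample, 99), seed=seed, ridge=ridge)
        return np.asarray(res.null_rho_sd)
    if method != "bootstrap":
        raise ValueError("method must be 'bootstrap' or 'permutation'")

    _, Sxx_inv_obs, Syy_inv_obs, Xdat, Ydat = _blocks_for_permutation(table, ridge)
    K = min(Xdat.shape[1], Ydat.shape[1])
    rng = np.random.default_rng(seed)
    n = table.n
    rhos = np.empty((n_resample, K))
    for r in range(n_resample):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            try:
                rhos[r] = _rho_from_data(Xdat[idx], Ydat[idx], ridge)
                break
            except np.linalg.LinAlgError:
                if attempt == max_retries:
                    raise
    return rhos.std(axis=0, ddof=1)


def _rho_from_data(X: np.ndarray, Y: np.ndarray, ridge: float) -> np.ndarray:
    """Canonical correlations of raw (possibly NaN-holed) binary blocks."""
    data = np.hstack([X, Y])
    Mv = np.isfinite(data).astype(float)
    A = np.where(Mv > 0, data, 0.0)
    m = Mv.T @ Mv
    if m.min() < 2:
        raise np.linalg.LinAlgError("pair with <2 complete cases")
    with np.errstate(invalid="ignore", divide="ignore"):
        cross = (A.T @ A) / m
        mean_i = (A.T @ Mv) / m
        V = cross - mean_i * mean_i.T
    V = (V + V.T) / 2.0
    p = X.shape[1]
    if np.any(np.diag(V) <= 0):
        raise np.linalg.LinAlgError("zero-variance column in resample")
    log: list[str] = []
    Sxx = _clip_psd(V[:p, :p], "S_xx", ridge, log)
    Syy = _clip_psd(V[p:, p:], "S_yy", ridge, log)
    lam = canonical_lambdas(np.linalg.inv(Sxx), np.linalg.inv(Syy), V[:p, p:])
    return np.sqrt(lam)
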