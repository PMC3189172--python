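"""CCA engine: whitened-SVD oracle, structural identities, redundancy."""

import numpy as np
import pytest
import scipy.linalg

from ginicca.cca import (
    canonical_lambdas,
    canonical_scores,
    cross_loading_from_identity,
    percent_of_variation,
    redundancy,
    sequential_wilks,
    solve_cca,
    structural_coefficients,
)
from ginicca.gini import AssociationMatrices, gini_correlation_matrix, gini_covariance_matrix
from ginicca.cohort import EXPOSURE_X, OUTCOME_Y

from conftest import make_table, random_binary_table


def assoc_from_cov(V: np.ndarray, p: int) -> AssociationMatrices:
    """Wrap a covariance matrix as AssociationMatrices with p X-variables."""
    d = V.shape[0]
    names = [f"x{i}" for i in range(p)] + [f"y{j}" for j in range(d - p)]
    assignment = {v: (EXPOSURE_X if v.startswith("x") else OUTCOME_Y) for v in names}
    return AssociationMatrices(
        variable_names=names,
        set_assignment=assignment,
        V=V,
        pairwise_n=np.full((d, d), 1000),
    )


def random_cov(rng: np.random.Generator, d: int) -> np.ndarray:
    W = rng.standard_normal((d, d + 2))
    return W @ W.T / (d + 2) + 0.5 * np.eye(d)


def whitened_svd_rho(Sxx, Sxy, Syy) -> np.ndarray:
    """Independent oracle: singular values of Sxx^-1/2 Sxy Syy^-1/2."""
    Wx = scipy.linalg.fractional_matrix_power(Sxx, -0.5)
    Wy = scipy.linalg.fractional_matrix_power(Syy, -0.5)
    s = scipy.linalg.svdvals(Wx @ Sxy @ Wy)
    return np.sort(s)[::-1][: min(Sxy.shape)]


class TestSolveCCA:
    def test_univariate_cca_is_absolute_correlation(self, rng):
        for r in (-0.6, 0.0, 0.4):
            V = np.array([[1.0, r], [r, 1.0]])
            sol = solve_cca(assoc_from_cov(V, 1))
            assert sol.K == 1
            assert sol.rho[0] == pytest.approx(abs(r), abs=1e-10)

    def test_independent_sets_give_zero(self, rng):
        V = np.zeros((5, 5))
        V[:2, :2] = random_cov(rng, 2)
        V[2:, 2:] = random_cov(rng, 3)
        sol = solve_cca(assoc_from_cov(V, 2))
        np.testing.assert_allclose(sol.rho, 0.0, atol=1e-8)

    def test_matches_whitened_svd_oracle(self, rng):
        for _ in range(30):
            p, q = rng.integers(1, 6, size=2)
            V = random_cov(rng, p + q)
            sol = solve_cca(assoc_from_cov(V, p))
            expected = whitened_svd_rho(V[:p, :p], V[:p, p:], V[p:, p:])
            np.testing.assert_allclose(sol.rho, expected, atol=1e-10)

    def test_both_eigenproblems_agree(self, rng):
        for _ in range(20):
            p, q = 4, 6
            V = random_cov(rng, p + q)
            Sxx_inv = np.linalg.inv(V[:p, :p])
            Syy_inv = np.linalg.inv(V[p:, p:])
            lx = canonical_lambdas(Sxx_inv, Syy_inv, V[:p, p:], side="x")
            ly = canonical_lambdas(Sxx_inv, Syy_inv, V[:p, p:], side="y")
            np.testing.assert_allclose(lx, ly, atol=1e-10)

    def test_invariant_under_within_set_recoding(self, rng):
        p, q = 3, 4
        V = random_cov(rng, p + q)
        base = solve_cca(assoc_from_cov(V, p)).rho
        for _ in range(10):
            Tx = rng.standard_normal((p, p))
            Ty = rng.standard_normal((q, q))
            while min(abs(np.linalg.det(Tx)), abs(np.linalg.det(Ty))) < 1e-3:
                Tx = rng.standard_normal((p, p))
                Ty = rng.standard_normal((q, q))
            T = scipy.linalg.block_diag(Tx, Ty)
            rho = solve_cca(assoc_from_cov(T @ V @ T.T, p)).rho
            np.testing.assert_allclose(rho, base, atol=1e-8)

    def test_rho1_dominates_pairwise_between_set_correlations(self, rng):
        table = random_binary_table(rng, 300, 4, 5)
        assoc = gini_correlation_matrix(gini_covariance_matrix(table))
        sol = solve_cca(assoc)
        between = assoc.R[: assoc.p, assoc.p :]
        assert sol.rho[0] >= np.abs(between).max() - 1e-10

    def test_weights_normalized_and_ordering(self, rng):
        V = random_cov(rng, 8)
        sol = solve_cca(assoc_from_cov(V, 3))
        Sxx, Syy = V[:3, :3], V[3:, 3:]
        for k in range(sol.K):
            assert sol.A[:, k] @ Sxx @ sol.A[:, k] == pytest.approx(1.0, abs=1e-8)
            assert sol.B[:, k] @ Syy @ sol.B[:, k] == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(sol.rho) <= 1e-12)
        assert np.all((sol.rho >= 0) & (sol.rho <= 1))

    def test_indefinite_block_repaired_and_logged(self, rng):
        V = random_cov(rng, 6)
        V[0, 1] = V[1, 0] = 10.0  # breaks PSD of S_xx
        assoc = assoc_from_cov(V, 3)
        sol = solve_cca(assoc)
        assert any("clipped" in entry for entry in sol.repair_log)
        assert np.all(sol.rho <= 1.0)


class TestScores:
    def test_score_correlation_reproduces_rho(self, rng):
        table = random_binary_table(rng, 400, 3, 4)
        sol = solve_cca(gini_covariance_matrix(table))
        U, V = canonical_scores(table, sol)
        for k in range(sol.K):
            # population-form correlation (divisor n) matches rho exactly
            r = (U[:, k] @ V[:, k] / len(U)) / (
                np.sqrt(U[:, k] @ U[:, k] / len(U)) * np.sqrt(V[:, k] @ V[:, k] / len(V))
            )
            assert r == pytest.approx(sol.rho[k], abs=1e-8)

    def test_missing_rows_get_nan_scores(self, rng):
        table = random_binary_table(rng, 50, 2, 2, missing=0.2)
        sol = solve_cca(gini_covariance_matrix(table))
        U, V = canonical_scores(table, sol)
        x_missing = ~np.all(np.isfinite(table.X), axis=1)
        assert np.all(np.isnan(U[x_missing]))
        assert np.all(np.isfinite(U[~x_missing]))

    def test_row_permutation_equivariance(self, rng):
        table = random_binary_table(rng, 60, 2, 3)
        sol = solve_cca(gini_covariance_matrix(table))
        U, V = canonical_scores(table, sol)
        perm = rng.permutation(60)
        shuffled = make_table(table.X[perm], table.Y[perm])
        U2, V2 = canonical_scores(shuffled, sol)
        np.testing.assert_allclose(U2, U[perm], atol=1e-12)
        np.testing.assert_allclose(V2, V[perm], atol=1e-12)


class TestStructural:
    def test_cross_loading_identity(self, rng):
        V = random_cov(rng, 9)
        sol = solve_cca(assoc_from_cov(V, 4))
        np.testing.assert_allclose(sol.cross_x, sol.loadings_x * sol.rho, atol=1e-8)
        np.testing.assert_allclose(sol.cross_y, sol.loadings_y * sol.rho, atol=1e-8)

    def test_sign_convention_dominant_x_loading_positive(self, rng):
        V = random_cov(rng, 7)
        sol = solve_cca(assoc_from_cov(V, 3))
        for k in range(sol.K):
            i = np.argmax(np.abs(sol.loadings_x[:, k]))
            assert sol.loadings_x[i, k] > 0

    def test_loadings_are_variable_variate_correlations(self, rng):
        table = random_binary_table(rng, 500, 3, 3)
        assoc = gini_covariance_matrix(table)
        sol = solve_cca(assoc)
        U, _ = canonical_scores(table, sol)
        Xc = table.X - table.X.mean(axis=0)
        for i in range(3):
            r = np.corrcoef(Xc[:, i], U[:, 0])[0, 1]
            assert r == pytest.approx(sol.loadings_x[i, 0], abs=1e-8)

    def test_percent_of_variation_arithmetic(self):
        assert percent_of_variation(0.94) == 88
        assert percent_of_variation(-0.52) == 27
        assert cross_loading_from_identity(0.71, 0.94) == pytest.approx(0.6674)

    def test_frame_covers_all_variables_and_variates(self, rng):
        V = random_cov(rng, 6)
        assoc = assoc_from_cov(V, 2)
        sol = solve_cca(assoc)
        frame = structural_coefficients(assoc, sol)
        assert len(frame) == (2 + 4) * sol.K
        assert set(frame["set"]) == {EXPOSURE_X, OUTCOME_Y}


class TestRedundancy:
    def test_zero_rho_gives_zero_redundancy(self):
        V = np.eye(4)
        sol = solve_cca(assoc_from_cov(V, 2))
        np.testing.assert_allclose(sol.redundancy_y_given_x, 0.0, atol=1e-12)

    def test_single_y_variable_attains_upper_bound(self, rng):
        V = np.array([[1.0, 0.5], [0.5, 1.0]])
        sol = solve_cca(assoc_from_cov(V, 1))
        assert sol.redundancy_y_given_x[0] == pytest.approx(sol.lam[0], abs=1e-10)

    def test_hand_computed_mean_squared_loading_formula(self):
        loadings = np.array([0.6, 0.8, 0.0])
        lam = 0.25
        expected = ((0.36 + 0.64 + 0.0) / 3) * lam
        assert expected == pytest.approx(1 / 12)
        # the solver's redundancy follows the same formula on its own loadings
        rng = np.random.default_rng(7)
        V = random_cov(rng, 6)
        sol = solve_cca(assoc_from_cov(V, 2))
        np.testing.assert_allclose(
            sol.redundancy_y_given_x,
            (sol.loadings_y**2).mean(axis=0) * sol.lam,
            atol=1e-12,
        )

    def test_redundancy_bounded_by_lambda(self, rng):
        V = random_cov(rng, 8)
        sol = solve_cca(assoc_from_cov(V, 3))
        assert np.all(sol.redundancy_y_given_x >= -1e-12)
        assert np.all(sol.redundancy_y_given_x <= sol.lam + 1e-12)
        frame = redundancy(assoc_from_cov(V, 3), sol)
        assert list(frame["variate"]) == [1, 2, 3]


class TestWilks:
    def test_sequential_product(self):
        lam = np.array([0.5, 0.2, 0.1])
        expected = [0.5 * 0.8 * 0.9, 0.8 * 0.9, 0.9]
        np.testing.assert_allclose(sequential_wilks(lam), expected, atol=1e-15)


class TestSklearnCrossCheck:
    def test_first_canonical_correlation_matches_sklearn(self, rng):
        sklearn_cca = pytest.importorskip("sklearn.cross_decomposition")
        table = random_binary_table(rng, 600, 3, 3)
        sol = solve_cca(gini_covariance_matrix(table))
        model = sklearn_cca.CCA(n_components=1, max_iter=2000, tol=1e-10)
        Xs, Ys = model.fit_transform(table.X, table.Y)
        r = abs(np.corrcoef(Xs[:, 0], Ys[:, 0])[0, 1])
        assert r == pytest.approx(sol.rho[0], abs=1e-6)
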