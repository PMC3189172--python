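import numpy as np
import pytest

from ginicca.cohort import EXPOSURE_X, OUTCOME_Y, CohortTable


def make_table(X: np.ndarray, Y: np.ndarray) -> CohortTable:
    """Build a CohortTable from raw X/Y blocks (NaN = missing)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = X.shape[0]
    x_names = [f"x{i}" for i in range(X.shape[1])]
    y_names = [f"y{j}" for j in range(Y.shape[1])]
    assignment = {v: EXPOSURE_X for v in x_names}
    assignment.update({v: OUTCOME_Y for v in y_names})
    return CohortTable(
        [f"s{i}" for i in range(n)], x_names + y_names, np.hstack([X, Y]), assignment
    )


def random_binary_table(
    rng: np.random.Generator, n: int, p: int, q: int, missing: float = 0.0
) -> CohortTable:
    """Random Bernoulli table; prevalences kept away from 0/1."""
    prev = rng.uniform(0.2, 0.8, size=p + q)
    data = (rng.random((n, p + q)) < prev).astype(float)
    # guard against constant columns at small n
    data[0, :] = 1.0
    data[1, :] = 0.0
    if missing > 0:
        mask = rng.random((n, p + q)) < missing
        mask[:2, :] = False
        data[mask] = np.nan
    return make_table(data[:, :p], data[:, p:])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
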