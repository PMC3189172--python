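"""Cohort data model: binary subjects-by-variables tables with missing values.

A :class:`CohortTable` holds a matrix of 0/1 indicators (presence/absence of
an exposure, symptom or diagnostic finding) over ``n`` subjects, with each
variable assigned to one of two sets: the exposure/demographic set ``X`` or
the symptom/clinical/diagnostic outcome set ``Y``.  Missing cells are stored
as ``NaN``.  Continuous variables (age in years, durations in days) are
dichotomized with explicit threshold rules before entering the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXPOSURE_X",
    "OUTCOME_Y",
    "CohortTable",
    "DichotomizationRule",
    "CohortConfigError",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "dichotomize",
    "summarize",
]

EXPOSURE_X = "exposure_X"
OUTCOME_Y = "outcome_Y"
_VALID_SETS = (EXPOSURE_X, OUTCOME_Y)

_OPERATORS = {
    "<=": np.less_equal,
    "<": np.less,
    ">=": np.greater_equal,
    ">": np.greater,
}


class CohortConfigError(ValueError):
    """Raised for an inconsistent set-assignment or rule configuration."""


class CohortParseError(ValueError):
    """Raised when a cohort CSV contains a cell that is not 0, 1 or missing."""


@dataclass(frozen=True)
class DichotomizationRule:
    """Threshold rule mapping a numeric column onto {0, 1, missing}.

    Values on the side of ``threshold`` selected by ``operator`` are coded 1
    (``code_one_when="satisfies"``, the default) or 0
    (``code_one_when="complement"``); the opposite side gets the other code.
    Boundary handling follows the operator's inclusivity exactly: with
    ``operator="<="`` and ``threshold=10``, an age of exactly 10 is coded 1.
    Missing numeric inputs stay missing.
    """

    variable: str
    threshold: float
    operator: str = "<="
    code_one_when: str = "satisfies"

    def __post_init__(self) -> None:
        if self.operator not in _OPERATORS:
            raise CohortConfigError(
                f"operator must be one of {sorted(_OPERATORS)}, got {self.operator!r}"
            )
        if self.code_one_when not in ("satisfies", "complement"):
            raise CohortConfigError(
                f"code_one_when must be 'satisfies' or 'complement', got {self.code_one_when!r}"
            )
        if not np.isfinite(self.threshold):
            raise CohortConfigError("threshold must be finite")


@dataclass
class CohortTable:
    """Subjects x variables table of binary indicators with a set split.

    ``values`` is an ``(n, p+q)`` float array over {0.0, 1.0, NaN}; NaN marks
    a missing measurement.  ``set_assignment`` maps every variable name to
    ``exposure_X`` or ``outcome_Y``.
    """

    subject_ids: list[str]
    variable_names: list[str]
    values: np.ndarray
    set_assignment: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CohortConfigError("values must be a 2-D matrix")
        if self.values.shape != (len(self.subject_ids), len(self.variable_names)):
            raise CohortConfigError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.variable_names)} variables"
            )
        if len(set(self.variable_names)) != len(self.variable_names):
            raise CohortConfigError("duplicated variable names")
        finite = self.values[np.isfinite(self.values)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            bad = finite[~np.isin(finite, (0.0, 1.0))][0]
            raise CohortParseError(f"non-binary cell value {bad!r}")
        for name in self.variable_names:
            assignment = self.set_assignment.get(name)
            if assignment not in _VALID_SETS:
                raise CohortConfigError(
                    f"variable {name!r} has invalid or missing set assignment "
                    f"{assignment!r}; expected one of {_VALID_SETS}"
                )
        extra = set(self.set_assignment) - set(self.variable_names)
        if extra:
            raise CohortConfigError(f"config assigns unknown variables: {sorted(extra)}")
        if self.p < 1 or self.q < 1:
            raise CohortConfigError("both sets must contain at least one variable")

    # -- basic geometry -------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def x_names(self) -> list[str]:
        return [v for v in self.variable_names if self.set_assignment[v] == EXPOSURE_X]

    @property
    def y_names(self) -> list[str]:
        return [v for v in self.variable_names if self.set_assignment[v] == OUTCOME_Y]

    @property
    def p(self) -> int:
        return len(self.x_names)

    @property
    def q(self) -> int:
        return len(self.y_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    @property
    def X(self) -> np.ndarray:
        idx = [self.variable_names.index(v) for v in self.x_names]
        return self.values[:, idx]

    @property
    def Y(self) -> np.ndarray:
        idx = [self.variable_names.index(v) for v in self.y_names]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.variable_names,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.variable_names == other.variable_names
            and self.set_assignment == other.set_assignment
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def read_cohort(
    csv_path: str | Path,
    config: Mapping[str, str],
    missing_token: str = "NA",
    rules: Sequence[DichotomizationRule] = (),
) -> CohortTable:
    """Read a cohort CSV (header row of variable names, one row per subject).

    The first column is taken as the subject identifier when it is named
    ``subject_id``; otherwise row numbers are used.  Cells equal to
    ``missing_token`` become missing; any other cell must parse as 0 or 1,
    except in columns covered by a :class:`DichotomizationRule`, which are
    parsed as numeric and thresholded.
    """
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    if df.columns.size and df.columns[0] == "subject_id":
        subject_ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    else:
        subject_ids = [str(i) for i in range(len(df))]
    variable_names = [str(c) for c in df.columns]

    missing = set(variable_names) - set(config)
    if missing:
        raise CohortConfigError(
            f"variables missing from set-assignment config: {sorted(missing)}"
        )

    rule_map = {r.variable: r for r in rules}
    unknown_rules = set(rule_map) - set(variable_names)
    if unknown_rules:
        raise CohortConfigError(
            f"dichotomization rules for unknown variables: {sorted(unknown_rules)}"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(variable_names):
        rule = rule_map.get(col)
        raw_cells = [c.strip() for c in df[col].tolist()]
        if rule is not None:
            numeric = np.empty(len(raw_cells))
            for i, cell in enumerate(raw_cells):
                if cell == missing_token:
                    numeric[i] = np.nan
                else:
                    try:
                        numeric[i] = float(cell)
                    except ValueError as exc:
                        raise CohortParseError(
                            f"cell {cell!r} at row {i + 1} (subject "
                            f"{subject_ids[i]!r}), column {col!r} is not numeric"
                        ) from exc
            values[:, j] = dichotomize(numeric, rule)
            continue
        for i, cell in enumerate(raw_cells):
            if cell == missing_token:
                values[i, j] = np.nan
            elif cell in ("0", "1"):
                values[i, j] = float(cell)
            else:
                raise CohortParseError(
                    f"cell {cell!r} at row {i + 1} (subject {subject_ids[i]!r}), "
                    f"column {col!r} is not 0, 1 or {missing_token!r}"
                )
    assignment = {v: config[v] for v in variable_names}
    return CohortTable(subject_ids, variable_names, values, assignment)


def write_cohort(
    table: CohortTable, csv_path: str | Path, missing_token: str = "NA"
) -> None:
    """Write a cohort back to the CSV dialect :func:`read_cohort` accepts."""
    df = table.to_frame()
    out = df.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    out.to_csv(csv_path)


def dichotomize(column: Sequence[float] | np.ndarray, rule: DichotomizationRule) -> np.ndarray:
    """Apply a threshold rule to a numeric column, yielding {0, 1, NaN}.

    Examples
    --------
    Ages ``[9, 10, 11, nan]`` with the rule "age <= 10 -> 1" give
    ``[1, 1, 0, nan]``: the boundary value belongs to the young group.
    """
    arr = np.asarray(column, dtype=float)
    if arr.size == 0:
        return arr.copy()
    out = np.full(arr.shape, np.nan)
    present = np.isfinite(arr)
    satisfied = _OPERATORS[rule.operator](arr[present], rule.threshold)
    if rule.code_one_when == "complement":
        satisfied = ~satisfied
    out[present] = satisfied.astype(float)
    return out


def summarize(table: CohortTable) -> pd.DataFrame:
    """Per-variable descriptive counts and percentages.

    Percentages use the full cohort size ``n`` as denominator (so the
    present/absent/missing percents of one variable add to 100 up to
    rounding); ``present_pct_nonmissing`` additionally reports the presence
    rate among subjects with an available measurement.  Percents are rounded
    to one decimal.
    """
    rows = []
    n = table.n
    for name in table.variable_names:
        col = table.column(name)
        miss = int(np.isnan(col).sum())
        present = int(np.nansum(col))
        absent = n - miss - present
        observed = n - miss
        rows.append(
            {
                "variable": name,
                "set": table.set_assignment[name],
                "present": present,
                "absent": absent,
                "missing": miss,
                "present_pct": round(100.0 * present / n, 1),
                "absent_pct": round(100.0 * absent / n, 1),
                "missing_pct": round(100.0 * miss / n, 1),
                "present_pct_nonmissing": (
                    round(100.0 * present / observed, 1) if observed else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
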