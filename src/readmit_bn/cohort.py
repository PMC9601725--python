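"""Patient cohort tables: typed categorical variables, validation, discretization.

A cohort is a rectangular table of per-patient observations. Analysis
variables are categorical with a fixed, declared level set
(:class:`VariableSpec`); raw clinical measurements (BMI in kg/m2, serum
albumin in g/dL, readmission counts) enter as numeric columns and are mapped
onto categories by :class:`DiscretizationRule` cut points of clinical
interest. Validation is complete-case: rows with a missing value in any
analysis column are dropped and counted, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSpec",
    "DiscretizationRule",
    "CohortSchema",
    "Cohort",
    "CohortValidationError",
    "read_cohort_table",
    "write_cohort",
    "discretize_cohort",
    "marginal_summary",
]


class CohortValidationError(ValueError):
    """A table cell, header, or schema violates the declared cohort contract."""


@dataclass(frozen=True)
class VariableSpec:
    """A named categorical analysis variable with a fixed, ordered level set.

    Parameters
    ----------
    name:
        Column identifier.
    levels:
        Category labels in display order; at least two, all distinct.
    ordered:
        Whether the levels carry an ordinal meaning (true for the
        readmission-count classes).
    """

    name: str
    levels: tuple[str, ...]
    ordered: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(lv) for lv in self.levels))
        if len(self.levels) < 2:
            raise CohortValidationError(
                f"variable {self.name!r} needs >=2 levels, got {len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise CohortValidationError(f"variable {self.name!r} has duplicate levels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def index(self, label: str) -> int:
        """Position of *label* in the level set (raises if unknown)."""
        try:
            return self.levels.index(label)
        except ValueError:
            raise CohortValidationError(
                f"{label!r} is not a level of variable {self.name!r}; "
                f"expected one of {list(self.levels)}"
            ) from None


@dataclass(frozen=True)
class DiscretizationRule:
    """Map a numeric column onto interval categories at fixed cut points.

    ``right_closed`` controls which side owns a boundary value: with
    ``right_closed=True`` the intervals are (-inf, c1], (c1, c2], ... so a
    value equal to a cut point falls in the *lower* class (albumin 3.5 g/dL
    -> "<=3.5"); with ``right_closed=False`` they are [..., c1), [c1, ...)
    so the boundary belongs to the *upper* class (BMI 25.0 -> ">=25").
    """

    source: str
    cut_points: tuple[float, ...]
    output: VariableSpec
    right_closed: bool = True
    units: str = ""

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cut_points)
        object.__setattr__(self, "cut_points", cuts)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise CohortValidationError(
                f"cut points for {self.source!r} must be strictly increasing: {cuts}"
            )
        if self.output.n_levels != len(cuts) + 1:
            raise CohortValidationError(
                f"rule for {self.source!r}: {len(cuts)} cut points imply "
                f"{len(cuts) + 1} levels but output declares {self.output.n_levels}"
            )

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Return the category label for each numeric value."""
        values = np.asarray(values, dtype=float)
        side = "left" if self.right_closed else "right"
        idx = np.searchsorted(self.cut_points, values, side=side)
        return np.asarray(self.output.levels, dtype=object)[idx]


@dataclass(frozen=True)
class CohortSchema:
    """Declared layout of an input table: categorical specs plus raw numeric columns."""

    categorical: tuple[VariableSpec, ...]
    numeric: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [v.name for v in self.categorical] + list(self.numeric)
        if len(set(names)) != len(names):
            raise CohortValidationError(f"schema has duplicate column names: {names}")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.categorical) + tuple(self.numeric)


class Cohort:
    """A validated table of per-patient observations.

    Every cell of a categorical column is guaranteed to be a declared level
    of its :class:`VariableSpec`; numeric passthrough columns are finite
    floats. ``n_dropped`` records rows removed by complete-case validation.
    """

    def __init__(
        self,
        variables: Sequence[VariableSpec],
        data: pd.DataFrame,
        *,
        numeric_columns: Sequence[str] = (),
        n_dropped: int = 0,
        validate: bool = True,
    ) -> None:
        self.variables = tuple(variables)
        self.numeric_columns = tuple(numeric_columns)
        self.n_dropped = int(n_dropped)
        cols = [v.name for v in self.variables] + list(self.numeric_columns)
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise CohortValidationError(f"table lacks declared columns {missing}")
        self.data = data.loc[:, cols].reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        for spec in self.variables:
            col = self.data[spec.name]
            allowed = set(spec.levels)
            bad = ~col.astype(object).isin(allowed)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"row {row}, column {spec.name!r}: value "
                    f"{col.iloc[row]!r} is not one of {list(spec.levels)}"
                )
        for name in self.numeric_columns:
            col = pd.to_numeric(self.data[name], errors="coerce")
            if col.isna().any():
                row = int(np.flatnonzero(col.isna().to_numpy())[0])
                raise CohortValidationError(
                    f"row {row}, column {name!r}: value "
                    f"{self.data[name].iloc[row]!r} is not numeric"
                )
            self.data[name] = col.astype(float)

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"no variable named {name!r}")

    def codes(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Integer level codes, shape (n, len(names)), in declared level order."""
        names = list(names) if names is not None else list(self.names)
        out = np.empty((self.n, len(names)), dtype=np.int64)
        for j, name in enumerate(names):
            spec = self.variable(name)
            mapping = {lv: i for i, lv in enumerate(spec.levels)}
            out[:, j] = self.data[name].map(mapping).to_numpy()
        return out

    def level_counts(self, name: str) -> pd.Series:
        spec = self.variable(name)
        counts = self.data[name].value_counts()
        return counts.reindex(spec.levels, fill_value=0).astype(int)

    def select(self, names: Sequence[str]) -> "Cohort":
        """Subset/reorder to the given analysis variables (numeric columns dropped)."""
        specs = [self.variable(n) for n in names]
        return Cohort(specs, self.data, n_dropped=self.n_dropped, validate=False)

    def to_csv(self, path_or_buf=None):
        return self.data.to_csv(path_or_buf, index=False)


def read_cohort_table(path, schema: CohortSchema) -> Cohort:
    """Read a UTF-8 CSV with header into a validated :class:`Cohort`.

    Rows with a missing value in any schema column are dropped (complete-case)
    and counted in ``Cohort.n_dropped``; an undeclared category label is an
    error naming the offending row and column.
    """
    try:
        raw = pd.read_csv(path, dtype=object, encoding="utf-8")
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read cohort table {path!r}: {exc}") from exc
    missing_cols = [c for c in schema.columns if c not in raw.columns]
    if missing_cols:
        raise CohortValidationError(
            f"header of {path!r} lacks declared columns {missing_cols}"
        )
    table = raw.loc[:, list(schema.columns)]
    # empty strings count as missing
    table = table.apply(lambda s: s.str.strip() if s.dtype == object else s)
    table = table.replace("", np.nan)
    complete = table.dropna()
    n_dropped = len(table) - len(complete)
    if n_dropped:
        logger.info("complete-case validation dropped %d row(s)", n_dropped)
    return Cohort(
        schema.categorical,
        complete,
        numeric_columns=schema.numeric,
        n_dropped=n_dropped,
    )


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as a UTF-8 CSV that :func:`read_cohort_table` reproduces."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(cohort.to_csv())


def discretize_cohort(raw: Cohort, rules: Iterable[DiscretizationRule]) -> Cohort:
    """Apply cut-point rules to numeric columns, yielding an all-categorical cohort.

    Categorical columns pass through untouched. Applying a rule to a column
    that is already categorical is rejected — re-binning categories is never
    silent.
    """
    rules = list(rules)
    categorical_names = set(raw.names)
    for rule in rules:
        if rule.source in categorical_names:
            raise CohortValidationError(
                f"column {rule.source!r} is already categorical; "
                "discretization applies only to declared numeric columns"
            )
        if rule.source not in raw.numeric_columns:
            raise CohortValidationError(
                f"rule source {rule.source!r} is not a numeric column of the cohort"
            )
    data = raw.data.copy()
    new_specs = []
    for rule in rules:
        data[rule.output.name] = rule.apply(data[rule.source].to_numpy())
        if rule.output.name != rule.source:
            data = data.drop(columns=[rule.source])
        new_specs.append(rule.output)
    untouched = [n for n in raw.numeric_columns if n not in {r.source for r in rules}]
    return Cohort(
        list(raw.variables) + new_specs,
        data,
        numeric_columns=untouched,
        n_dropped=raw.n_dropped,
    )


def marginal_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-variable level counts and proportions (the cohort-description table).

    Returns a frame with columns ``variable, level, count, proportion``;
    counts sum to n within each variable.
    """
    if cohort.n == 0:
        logger.warning("marginal_summary of an empty cohort")
        return pd.DataFrame(columns=["variable", "level", "count", "proportion"])
    rows = []
    for spec in cohort.variables:
        counts = cohort.level_counts(spec.name)
        for level, count in counts.items():
            rows.append(
                {
                    "variable": spec.name,
                    "level": level,
                    "count": int(count),
                    "proportion": count / cohort.n,
                }
            )
    return pd.DataFrame(rows)
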