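"""Pairwise Pearson chi-square screening of categorical associations.

Each unordered variable pair gets one test of independence on its r×s
contingency table; a pair is flagged when p ≤ α (default 0.05, with a
secondary reporting tier at 0.10). No continuity correction is applied, so
2×2 tables are treated exactly like larger ones — this can diverge from
software that applies Yates' correction by default. Decisions are per pair,
with no multiple-testing adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "ChiSquareResult",
    "AssociationMatrix",
    "DegenerateTableError",
    "chi_square_test",
    "association_matrix",
]


class DegenerateTableError(ValueError):
    """The contingency table has fewer than two levels on one margin."""


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square test of independence on one contingency table."""

    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    dropped_levels: tuple[tuple[str, str], ...] = ()
    min_expected: float = float("nan")

    @property
    def small_expected(self) -> bool:
        """True when some expected cell count falls below the classic threshold 5."""
        return self.min_expected < 5.0


def chi_square_test(cohort: Cohort, a: str, b: str) -> ChiSquareResult:
    """Test independence of variables *a* and *b* with Pearson's chi-square.

    The statistic is Σ (observed − expected)²/expected over the r×s table
    with df = (r−1)(s−1); the p-value comes from the chi-square upper tail.
    Levels with zero marginal count are dropped with a warning; a table left
    with a single level on either margin is degenerate.
    """
    if a == b:
        raise ValueError("chi_square_test requires two distinct variables")
    spec_a, spec_b = cohort.variable(a), cohort.variable(b)
    table = pd.crosstab(cohort.data[a], cohort.data[b])
    table = table.reindex(index=list(spec_a.levels), columns=list(spec_b.levels), fill_value=0)
    dropped = []
    for name, axis_levels, axis in ((a, spec_a.levels, 0), (b, spec_b.levels, 1)):
        margins = table.sum(axis=1 - axis)
        for level in axis_levels:
            if margins[level] == 0:
                dropped.append((name, level))
    if dropped:
        logger.warning("dropping zero-count level(s) from %s×%s table: %s", a, b, dropped)
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError(
            f"{a}×{b} table is {table.shape[0]}×{table.shape[1]} after dropping "
            "empty levels; independence is undefined"
        )
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    min_expected = float(np.min(res.expected_freq))
    if min_expected < 5.0:
        logger.warning(
            "%s×%s: smallest expected count %.2f < 5; chi-square approximation is rough",
            a, b, min_expected,
        )
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        table=table,
        dropped_levels=tuple(dropped),
        min_expected=min_expected,
    )


@dataclass(frozen=True)
class AssociationMatrix:
    """All pairwise screening results plus the binary significance flags."""

    variables: tuple[str, ...]
    pairs: pd.DataFrame  # columns: a, b, statistic, df, p_value, flag, tier
    alpha: float
    secondary_alpha: float

    def flag(self, a: str, b: str) -> int:
        row = self._row(a, b)
        return int(row["flag"])

    def p_value(self, a: str, b: str) -> float:
        return float(self._row(a, b)["p_value"])

    def _row(self, a: str, b: str) -> pd.Series:
        mask = ((self.pairs["a"] == a) & (self.pairs["b"] == b)) | (
            (self.pairs["a"] == b) & (self.pairs["b"] == a)
        )
        match = self.pairs[mask]
        if match.empty:
            raise KeyError(f"no screened pair ({a}, {b})")
        return match.iloc[0]

    def to_table(self) -> pd.DataFrame:
        """Lower-triangular 0/1 layout with '-' on and above the diagonal."""
        out = pd.DataFrame("-", index=self.variables, columns=self.variables)
        order = {v: i for i, v in enumerate(self.variables)}
        for _, row in self.pairs.iterrows():
            a, b = row["a"], row["b"]
            lo, hi = (a, b) if order[a] < order[b] else (b, a)
            out.loc[hi, lo] = str(int(row["flag"]))
        return out

    def to_csv(self, path) -> None:
        self.to_table().to_csv(path, index_label="")


def association_matrix(
    cohort: Cohort,
    alpha: float = 0.05,
    secondary_alpha: float = 0.10,
) -> AssociationMatrix:
    """Screen every unordered variable pair; flag = 1 iff p ≤ α.

    A borderline p exactly at α counts as significant. The ``tier`` column
    carries ``**`` for p ≤ α, ``*`` for α < p ≤ the secondary level, and
    ``""`` otherwise — the annotation scheme used on reported graphs.
    """
    names = cohort.names
    if len(names) < 2:
        raise ValueError("association screening needs at least two variables")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = chi_square_test(cohort, a, b)
            flag = int(res.p_value <= alpha)
            if flag:
                tier = "**"
            elif res.p_value <= secondary_alpha:
                tier = "*"
            else:
                tier = ""
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "flag": flag,
                    "tier": tier,
                    "min_expected": res.min_expected,
                }
            )
    return AssociationMatrix(names, pd.DataFrame(rows), alpha, secondary_alpha)
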