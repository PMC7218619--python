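"""Lexis tables for age-period-cohort (APC) count data.

An APC table is a rectangular age-group x calendar-period grid holding, for one
stratum (e.g. one gender), the number of subjects at risk ``n`` and the number
of events ``y`` in every cell.  Birth cohorts run along the grid's diagonals;
with ``I`` age groups, ``J`` periods and ``M`` the ratio of age-interval width
to period-interval width, the cell ``(i, j)`` belongs to the cohort diagonal

    k = M * (I - i) + j,

with ``i = 1`` the youngest age group, so larger ``k`` means a more recently
born cohort.  Over the full grid this generates ``K = M * (I - 1) + J``
distinct cohort indices; consecutive diagonals overlap in birth years, so they
can additionally be grouped into disjoint decade-of-birth labels.

This module provides the table container, the cohort bookkeeping, marginal
observed rates (by age, period, cohort, or in total), and the CSV interchange
format used by the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroup",
    "Period",
    "APCTable",
    "RateSeries",
    "TableValidationError",
    "cohort_index",
    "count_cohorts",
    "cohort_index_grid",
    "birth_interval",
    "decade_cohort_labels",
    "observed_rates",
    "aggregate_tables",
    "read_table_csv",
    "write_table_csv",
    "write_rates_csv",
]

Margin = Literal["age", "period", "cohort", "total"]


class TableValidationError(ValueError):
    """Raised when a table or interchange file violates the APC schema."""


@dataclass(frozen=True)
class AgeGroup:
    """One age interval, closed on both ends (e.g. 31-35)."""

    index: int
    start_age: int
    end_age: int

    def __post_init__(self) -> None:
        if self.start_age > self.end_age:
            raise TableValidationError(
                f"age group {self.index}: start_age {self.start_age} > end_age {self.end_age}"
            )

    @property
    def width(self) -> int:
        return self.end_age - self.start_age + 1

    @property
    def label(self) -> str:
        return f"{self.start_age}-{self.end_age}"


@dataclass(frozen=True)
class Period:
    """One calendar-period interval, closed on both ends (e.g. 1991-1995)."""

    index: int
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise TableValidationError(
                f"period {self.index}: start_year {self.start_year} > end_year {self.end_year}"
            )

    @property
    def width(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def label(self) -> str:
        return f"{self.start_year}-{self.end_year}"


def _check_contiguous(indices: Sequence[int], what: str) -> None:
    if list(indices) != list(range(1, len(indices) + 1)):
        raise TableValidationError(f"{what} indices must be contiguous from 1, got {list(indices)}")


@dataclass
class APCTable:
    """Age x period grid of at-risk counts ``n`` and event counts ``y`` for one stratum.

    The last age group may be wider than the others (an open-ended top class
    such as ">70"); all other widths must be equal.  ``m_ratio`` — the ratio of
    the common age width to the period width — is only defined when that ratio
    is a positive integer; cohort-indexed operations require it.
    """

    stratum: str
    age_groups: list[AgeGroup]
    periods: list[Period]
    n: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        I, J = len(self.age_groups), len(self.periods)
        if self.n.shape != (I, J) or self.y.shape != (I, J):
            raise TableValidationError(
                f"count matrices must have shape ({I}, {J}); got n {self.n.shape}, y {self.y.shape}"
            )
        _check_contiguous([a.index for a in self.age_groups], "age group")
        _check_contiguous([p.index for p in self.periods], "period")
        widths = {a.width for a in self.age_groups[:-1]}
        if len(widths) > 1:
            raise TableValidationError(f"age-group widths differ: {sorted(widths)}")
        if len(self.age_groups) > 1 and self.age_groups[-1].width < self.age_groups[0].width:
            raise TableValidationError("last age group narrower than the common width")
        pwidths = {p.width for p in self.periods}
        if len(pwidths) > 1:
            raise TableValidationError(f"period widths differ: {sorted(pwidths)}")
        for a in range(1, I):
            if self.age_groups[a].start_age != self.age_groups[a - 1].end_age + 1:
                raise TableValidationError(
                    f"age groups {a} and {a + 1} are not adjacent"
                )
        if np.any(self.n < 0) or np.any(self.y < 0):
            raise TableValidationError("counts must be non-negative")
        bad = np.argwhere(self.y > self.n)
        if bad.size:
            rows = ", ".join(
                f"(age {self.age_groups[i].label}, period {self.periods[j].label}: "
                f"y={self.y[i, j]} > n={self.n[i, j]})"
                for i, j in bad[:5]
            )
            raise TableValidationError(f"event count exceeds at-risk count in cells: {rows}")

    @property
    def I(self) -> int:  # noqa: E743 - field notation
        return len(self.age_groups)

    @property
    def J(self) -> int:
        return len(self.periods)

    @property
    def age_width(self) -> int:
        return self.age_groups[0].width

    @property
    def period_width(self) -> int:
        return self.periods[0].width

    @property
    def m_ratio(self) -> int | None:
        """Age-width / period-width, or None when not a positive integer."""
        if self.age_width % self.period_width == 0:
            return self.age_width // self.period_width
        return None

    @property
    def K(self) -> int:
        m = self._require_m()
        return count_cohorts(self.I, self.J, m)

    def _require_m(self) -> int:
        m = self.m_ratio
        if m is None:
            raise TableValidationError(
                f"cohort operations need an integer age/period width ratio; "
                f"widths are {self.age_width} and {self.period_width}"
            )
        return m


def cohort_index(i: int, j: int, I: int, M: int) -> int:
    """Cohort diagonal index ``k = M * (I - i) + j`` of the cell ``(i, j)``.

    ``i = 1`` is the youngest age group and ``j = 1`` the earliest period, so
    the largest ``k`` labels the most recently born cohort.
    """
    if M < 1:
        raise ValueError(f"interval ratio M must be >= 1, got {M}")
    if not 1 <= i <= I:
        raise IndexError(f"age index i={i} outside 1..I={I}")
    if j < 1:
        raise IndexError(f"period index j={j} below 1")
    return M * (I - i) + j


def count_cohorts(I: int, J: int, M: int) -> int:
    """Number of distinct cohort indices on a full ``I x J`` grid: ``M*(I-1) + J``."""
    if I < 1 or J < 1 or M < 1:
        raise ValueError(f"I, J, M must all be >= 1, got I={I}, J={J}, M={M}")
    return M * (I - 1) + J


def cohort_index_grid(table: APCTable) -> np.ndarray:
    """``(I, J)`` array of 1-based cohort indices for every cell."""
    m = table._require_m()
    i = np.arange(1, table.I + 1)[:, None]
    j = np.arange(1, table.J + 1)[None, :]
    return m * (table.I - i) + j


def birth_interval(table: APCTable, k: int) -> tuple[int, int]:
    """Birth-year interval ``[period_start - age_end, period_end - age_start]`` of diagonal ``k``.

    Taken as the union over all observed cells on the diagonal; consecutive
    diagonals overlap, which is why disjoint decade labels are also provided.
    """
    grid = cohort_index_grid(table)
    cells = np.argwhere(grid == k)
    if not cells.size:
        raise IndexError(f"cohort index {k} not present on the {table.I}x{table.J} grid")
    starts = [table.periods[j].start_year - table.age_groups[i].end_age for i, j in cells]
    ends = [table.periods[j].end_year - table.age_groups[i].start_age for i, j in cells]
    return min(starts), max(ends)


def decade_cohort_labels(table: APCTable) -> dict[int, str]:
    """Group the overlapping cohort diagonals into disjoint 10-year birth intervals.

    Each diagonal is assigned to the decade containing the midpoint of its
    birth-year span, with decades anchored at the earliest birth year on the
    grid.  For the 14 x 5 grid of ages 31-100 and periods 1991-2015 this gives
    the nine disjoint labels 1891-1900, 1901-1910, ..., 1971-1980.
    """
    m = table._require_m()
    K = count_cohorts(table.I, table.J, m)
    base = min(birth_interval(table, k)[0] for k in range(1, K + 1))
    labels: dict[int, str] = {}
    for k in range(1, K + 1):
        lo, hi = birth_interval(table, k)
        mid = (lo + hi) / 2
        d = int((mid - base) // 10)
        labels[k] = f"{base + 10 * d}-{base + 10 * d + 9}"
    return labels


@dataclass
class RateSeries:
    """Marginal observed rates: numerator / denominator per level of one margin.

    Rates are stored at full precision; levels with an empty denominator are
    reported as NaN, never as zero.
    """

    margin: Margin
    labels: list[str]
    numerators: np.ndarray
    denominators: np.ndarray
    rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.numerators = np.asarray(self.numerators, dtype=np.int64)
        self.denominators = np.asarray(self.denominators, dtype=np.int64)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(
                self.denominators > 0,
                self.numerators / np.maximum(self.denominators, 1),
                np.nan,
            )
        self.rates = r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "margin": self.margin,
                "level_label": self.labels,
                "numerator": self.numerators,
                "denominator": self.denominators,
                "rate": self.rates,
            }
        )


def observed_rates(table: APCTable, margin: Margin) -> RateSeries:
    """Observed event rates along one margin of the table.

    Sums integer numerators and denominators over all cells mapping to each
    margin level (cohort levels via the diagonal index), then divides.
    """
    if margin == "total":
        return RateSeries("total", ["total"], [int(table.y.sum())], [int(table.n.sum())])
    if margin == "age":
        labels = [a.label for a in table.age_groups]
        return RateSeries("age", labels, table.y.sum(axis=1), table.n.sum(axis=1))
    if margin == "period":
        labels = [p.label for p in table.periods]
        return RateSeries("period", labels, table.y.sum(axis=0), table.n.sum(axis=0))
    if margin == "cohort":
        grid = cohort_index_grid(table)
        K = table.K
        num = np.zeros(K, dtype=np.int64)
        den = np.zeros(K, dtype=np.int64)
        np.add.at(num, grid.ravel() - 1, table.y.ravel())
        np.add.at(den, grid.ravel() - 1, table.n.ravel())
        labels = [f"{birth_interval(table, k)[0]}-{birth_interval(table, k)[1]}" for k in range(1, K + 1)]
        return RateSeries("cohort", labels, num, den)
    raise ValueError(f"unknown margin {margin!r}")


def aggregate_tables(tables: Sequence[APCTable], stratum: str = "combined") -> APCTable:
    """Pool several strata cell-wise.  Pooling is always explicit, never implied."""
    first = tables[0]
    for t in tables[1:]:
        if [a.label for a in t.age_groups] != [a.label for a in first.age_groups] or [
            p.label for p in t.periods
        ] != [p.label for p in first.periods]:
            raise TableValidationError("tables to aggregate must share the same grid")
    n = sum(t.n for t in tables)
    y = sum(t.y for t in tables)
    return APCTable(stratum, list(first.age_groups), list(first.periods), n, y)


_CSV_COLUMNS = ["stratum", "age_start", "age_end", "period_start", "period_end", "n_at_risk", "cases"]


def read_table_csv(path: str | Path) -> list[APCTable]:
    """Read the interchange CSV (one row per cell) into one APCTable per stratum.

    Validates the schema: mandatory header, complete rectangular grid per
    stratum, no duplicate cells, ``cases <= n_at_risk``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"interchange CSV missing columns: {missing}")
    bad = df[df["cases"] > df["n_at_risk"]]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad.index[:5])  # +2: header + 0-base
        raise TableValidationError(f"cases > n_at_risk at file line(s) {rows}")
    dup = df.duplicated(subset=["stratum", "age_start", "period_start"])
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup][:5])
        raise TableValidationError(f"duplicate (stratum, age, period) cells at file line(s) {rows}")

    tables = []
    for stratum, sub in df.groupby("stratum", sort=False):
        ages = sorted({(int(r.age_start), int(r.age_end)) for r in sub.itertuples()})
        pers = sorted({(int(r.period_start), int(r.period_end)) for r in sub.itertuples()})
        if len(sub) != len(ages) * len(pers):
            raise TableValidationError(
                f"stratum {stratum!r}: expected a complete {len(ages)}x{len(pers)} grid "
                f"({len(ages) * len(pers)} cells), found {len(sub)} rows"
            )
        age_groups = [AgeGroup(ix + 1, a0, a1) for ix, (a0, a1) in enumerate(ages)]
        periods = [Period(ix + 1, p0, p1) for ix, (p0, p1) in enumerate(pers)]
        a_pos = {a: ix for ix, a in enumerate(ages)}
        p_pos = {p: ix for ix, p in enumerate(pers)}
        n = np.zeros((len(ages), len(pers)), dtype=np.int64)
        y = np.zeros_like(n)
        for r in sub.itertuples():
            i = a_pos[(int(r.age_start), int(r.age_end))]
            j = p_pos[(int(r.period_start), int(r.period_end))]
            n[i, j] = int(r.n_at_risk)
            y[i, j] = int(r.cases)
        tables.append(APCTable(str(stratum), age_groups, periods, n, y))
    return tables


def write_table_csv(tables: Iterable[APCTable], path: str | Path) -> None:
    """Write tables in the interchange CSV schema; inverse of :func:`read_table_csv`."""
    rows = []
    for t in tables:
        for i, a in enumerate(t.age_groups):
            for j, p in enumerate(t.periods):
                rows.append(
                    (t.stratum, a.start_age, a.end_age, p.start_year, p.end_year, t.n[i, j], t.y[i, j])
                )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def write_rates_csv(series: Iterable[RateSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)
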