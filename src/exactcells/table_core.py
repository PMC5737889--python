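"""Contingency-table container, delimited-text I/O, expected counts and the
omnibus Pearson chi-squared test.

The central object is :class:`ContingencyTable`, an immutable R x C matrix of
non-negative integer counts with row/column labels.  Margins (row totals
``m_i``, column totals ``n_j``, grand total ``N``) are always derived from the
counts themselves; margin rows/columns present in input files are detected and
stripped, never trusted.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "ChiSquaredResult",
    "TableValidationError",
    "DegenerateMarginError",
    "read_table",
    "write_table",
    "expected_counts",
    "chi_squared_test",
]


class TableValidationError(ValueError):
    """Raised when input counts violate the contingency-table contract."""


class DegenerateMarginError(ValueError):
    """Raised when a zero (or total-absorbing) margin makes a statistic undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """An R x C table of non-negative integer counts with labels.

    Parameters
    ----------
    counts
        Integer matrix with at least 2 rows and 2 columns and grand total >= 1.
    row_labels, col_labels
        Optional label sequences; defaults are ``R1..`` / ``C1..``.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __init__(
        self,
        counts,
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> None:
        arr = np.asarray(counts)
        if arr.ndim != 2:
            raise TableValidationError(
                f"counts must be a 2-D matrix, got {arr.ndim} dimension(s)"
            )
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise TableValidationError(
                f"a contingency table needs at least 2 rows and 2 columns, "
                f"got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(np.asarray(arr, dtype=float))
            bad = np.argwhere(~np.isclose(np.asarray(arr, dtype=float), rounded))
            if bad.size:
                i, j = bad[0]
                raise TableValidationError(
                    f"cell ({i + 1},{j + 1}) has non-integer count {arr[i, j]!r}"
                )
            arr = rounded.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise TableValidationError(
                f"cell ({i + 1},{j + 1}) has negative count {arr[i, j]}"
            )
        if arr.sum() < 1:
            raise TableValidationError("grand total must be at least 1")
        R, C = arr.shape
        rl = tuple(str(x) for x in row_labels) if row_labels is not None else tuple(
            f"R{i + 1}" for i in range(R)
        )
        cl = tuple(str(x) for x in col_labels) if col_labels is not None else tuple(
            f"C{j + 1}" for j in range(C)
        )
        if len(rl) != R or len(cl) != C:
            raise TableValidationError(
                f"label lengths {len(rl)}x{len(cl)} do not match shape {R}x{C}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "row_labels", rl)
        object.__setattr__(self, "col_labels", cl)

    # -- derived margins -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        """Row margins m_i."""
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Column margins n_j."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        """Grand total N."""
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        return expected_counts(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ContingencyTable({self.n_rows}x{self.n_cols}, N={self.total}, "
            f"rows={list(self.row_labels)}, cols={list(self.col_labels)})"
        )


@dataclass(frozen=True)
class ChiSquaredResult:
    """Pearson chi-squared omnibus test of independence."""

    statistic: float
    df: int
    p_value: float


def _is_number(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def read_table(
    source, delimiter: str | None = None
) -> ContingencyTable:
    """Read an R x C count matrix from delimited text.

    Layout: rows x columns; an optional header row (detected when the first
    row is non-numeric) and an optional leading label column (detected when
    the first column is non-numeric).  A trailing margin row/column equal to
    the sum of the others is stripped with a logged notice, provided at least
    a 2 x 2 core remains.

    Parameters
    ----------
    source
        File path, string of text, or open text handle.
    delimiter
        Field separator; ``None`` auto-detects comma vs. tab.
    """
    if isinstance(source, (str, Path)) and not (
        isinstance(source, str) and ("\n" in source or "," in source or "\t" in source)
    ):
        text = Path(source).read_text()
    elif isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    text = text.strip("\n")
    if not text.strip():
        raise TableValidationError("empty input: no table found")
    if delimiter is None:
        first = text.splitlines()[0]
        delimiter = "\t" if first.count("\t") >= first.count(",") else ","
    try:
        df = pd.read_csv(
            io.StringIO(text), sep=delimiter, header=None, dtype=str,
            skip_blank_lines=True, comment="#",
        )
    except pd.errors.EmptyDataError as exc:
        raise TableValidationError("empty input: no table found") from exc
    cells = df.fillna("").map(str.strip) if hasattr(df, "map") else df.fillna("").applymap(str.strip)

    col_labels: list[str] | None = None
    row_labels: list[str] | None = None
    def _all_labels(tokens: list[str]) -> bool:
        nonempty = [tok for tok in tokens if tok != ""]
        return bool(nonempty) and all(not _is_number(tok) for tok in nonempty)

    first_row = cells.iloc[0].tolist()
    has_header = _all_labels(first_row)
    if has_header:
        header = first_row
        cells = cells.iloc[1:].reset_index(drop=True)
        if len(cells) == 0:
            raise TableValidationError("input contains a header but no data rows")
    first_col = cells.iloc[:, 0].tolist()
    has_label_col = _all_labels(first_col)
    if has_label_col:
        row_labels = first_col
        cells = cells.iloc[:, 1:]
    if has_header:
        col_labels = header[1:] if has_label_col and len(header) == cells.shape[1] + 1 else header
        col_labels = [str(c) for c in col_labels[-cells.shape[1]:]]

    values = np.empty(cells.shape, dtype=float)
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            tok = cells.iat[i, j]
            if not _is_number(tok):
                raise TableValidationError(
                    f"cell ({i + 1},{j + 1}) is not numeric: {tok!r}"
                )
            values[i, j] = float(tok)
    frac = values - np.rint(values)
    bad = np.argwhere(np.abs(frac) > 0)
    if bad.size:
        i, j = bad[0]
        raise TableValidationError(
            f"cell ({i + 1},{j + 1}) has non-integer count {values[i, j]}"
        )
    counts = np.rint(values).astype(np.int64)

    # strip a trailing margin row / column (never trusted, always re-derived)
    if counts.shape[0] >= 3 and np.array_equal(counts[-1], counts[:-1].sum(axis=0)):
        logger.info("dropping trailing row equal to the column sums (margin row)")
        counts = counts[:-1]
        if row_labels is not None:
            row_labels = row_labels[:-1]
    if counts.shape[1] >= 3 and np.array_equal(
        counts[:, -1], counts[:, :-1].sum(axis=1)
    ):
        logger.info("dropping trailing column equal to the row sums (margin column)")
        counts = counts[:, :-1]
        if col_labels is not None:
            col_labels = col_labels[: counts.shape[1]]

    return ContingencyTable(counts, row_labels, col_labels)


def write_table(table: ContingencyTable, handle, delimiter: str = ",") -> None:
    """Serialize a table back to delimited text with its labels."""
    close = False
    if isinstance(handle, (str, Path)):
        handle = open(handle, "w")
        close = True
    try:
        handle.write(delimiter.join([""] + list(table.col_labels)) + "\n")
        for lab, row in zip(table.row_labels, table.counts):
            handle.write(delimiter.join([lab] + [str(int(v)) for v in row]) + "\n")
    finally:
        if close:
            handle.close()


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected counts under independence: e_ij = m_i * n_j / N."""
    m = table.row_totals.astype(float)
    n = table.col_totals.astype(float)
    return np.outer(m, n) / table.total


def chi_squared_test(table: ContingencyTable) -> ChiSquaredResult:
    """Pearson chi-squared test of independence, without continuity correction.

    statistic = sum_ij (x_ij - e_ij)^2 / e_ij with (R-1)(C-1) degrees of
    freedom.  Requires all margins strictly positive (every expected count
    must be > 0); zero rows or columns are rejected rather than dropped.
    """
    if (table.row_totals == 0).any() or (table.col_totals == 0).any():
        raise DegenerateMarginError(
            "table has a zero row or column margin; remove empty levels first"
        )
    e = expected_counts(table)
    stat = float(((table.counts - e) ** 2 / e).sum())
    df = (table.n_rows - 1) * (table.n_cols - 1)
    p = float(stats.chi2.sf(stat, df))
    return ChiSquaredResult(statistic=stat, df=df, p_value=p)
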