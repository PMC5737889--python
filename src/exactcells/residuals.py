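"""Per-cell residual statistics and their asymptotic p-values.

Three residuals are defined for cell (i, j) of an R x C table with observed
count x_ij, expected count e_ij = m_i n_j / N:

* raw residual        T_RawR = x_ij - e_ij
* standardized        T_StdR = (x_ij - e_ij) / sqrt(e_ij)
* adjusted            T_AdjR = (x_ij - e_ij) / sqrt(e_ij (1 - m_i/N)(1 - n_j/N))

T_StdR and T_AdjR are asymptotically standard normal under independence, so a
two-sided normal p-value applies; equivalently the squared statistic is
referred to a chi-squared distribution with 1 degree of freedom.  Because the
extra variance factors (1 - m_i/N)(1 - n_j/N) are below one, |T_AdjR| >=
|T_StdR| and the adjusted test is always at least as anti-conservative.

Signed residuals are the canonical representation; squared values and their
chi-squared(1)-form p-values are derived views (report tables print the
squares).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .table_core import ContingencyTable, DegenerateMarginError, expected_counts

__all__ = [
    "CellResiduals",
    "raw_residual",
    "std_residual",
    "adj_residual",
    "asymptotic_pvalue",
    "cell_residuals",
    "residual_matrices",
]


@dataclass(frozen=True)
class CellResiduals:
    """Signed residuals for one cell, with squared and p-value views."""

    raw: float
    std: float
    adj: float

    @property
    def raw_sq(self) -> float:
        return self.raw**2

    @property
    def std_sq(self) -> float:
        return self.std**2

    @property
    def adj_sq(self) -> float:
        return self.adj**2

    @property
    def p_std(self) -> float:
        return asymptotic_pvalue(self.std)

    @property
    def p_adj(self) -> float:
        return asymptotic_pvalue(self.adj)


def raw_residual(table: ContingencyTable, i: int, j: int) -> float:
    """Observed minus expected count, x_ij - e_ij."""
    e = table.row_totals[i] * table.col_totals[j] / table.total
    return float(table.counts[i, j] - e)


def std_residual(table: ContingencyTable, i: int, j: int) -> float:
    """Raw residual scaled by sqrt(e_ij); its squares sum to the Pearson statistic."""
    e = table.row_totals[i] * table.col_totals[j] / table.total
    if e == 0:
        raise DegenerateMarginError(
            f"expected count is zero at cell ({i},{j}); zero margin"
        )
    return raw_residual(table, i, j) / np.sqrt(e)


def adj_residual(table: ContingencyTable, i: int, j: int) -> float:
    """Raw residual divided by its null standard error; asymptotically N(0,1)."""
    N = table.total
    m = int(table.row_totals[i])
    n = int(table.col_totals[j])
    e = m * n / N
    if e == 0:
        raise DegenerateMarginError(
            f"expected count is zero at cell ({i},{j}); zero margin"
        )
    if m == N or n == N:
        raise DegenerateMarginError(
            f"margin absorbs the whole sample at cell ({i},{j}); "
            "adjusted residual has zero variance"
        )
    var = e * (1 - m / N) * (1 - n / N)
    return raw_residual(table, i, j) / np.sqrt(var)


def asymptotic_pvalue(t: float) -> float:
    """Two-sided standard-normal p-value of a signed residual.

    Identical to the upper-tail chi-squared(1 df) probability of t^2.
    """
    return float(2.0 * stats.norm.sf(abs(t)))


def cell_residuals(table: ContingencyTable, i: int, j: int) -> CellResiduals:
    return CellResiduals(
        raw=raw_residual(table, i, j),
        std=std_residual(table, i, j),
        adj=adj_residual(table, i, j),
    )


def residual_matrices(table: ContingencyTable) -> dict[str, np.ndarray]:
    """All signed residuals and asymptotic p-values, vectorized over the table.

    Returns a dict with keys ``raw``, ``std``, ``adj`` (signed R x C matrices)
    and ``p_std``, ``p_adj`` (two-sided normal p-values).
    """
    N = table.total
    m = table.row_totals.astype(float)
    n = table.col_totals.astype(float)
    if (m == 0).any() or (n == 0).any():
        raise DegenerateMarginError("zero margin; remove empty levels first")
    if (m == N).any() or (n == N).any():
        raise DegenerateMarginError("a margin absorbs the whole sample")
    e = expected_counts(table)
    raw = table.counts - e
    std = raw / np.sqrt(e)
    adj = raw / np.sqrt(e * (1 - m / N)[:, None] * (1 - n / N)[None, :])
    return {
        "raw": raw,
        "std": std,
        "adj": adj,
        "p_std": 2.0 * stats.norm.sf(np.abs(std)),
        "p_adj": 2.0 * stats.norm.sf(np.abs(adj)),
    }
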