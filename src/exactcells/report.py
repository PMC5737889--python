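"""Post-hoc report assembly: one row per cell, sorted like the field's
customary presentation (largest squared adjusted residual first), with the
overall chi-squared test and per-method multiplicity decisions attached."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exact_posthoc import exact_pvalue_matrix
from .multiplicity import (
    MultiplicityDecision,
    bonferroni_decisions,
    holm_decisions,
    simes_decisions,
)
from .residuals import residual_matrices
from .table_core import ChiSquaredResult, ContingencyTable, chi_squared_test

__all__ = ["PosthocReport", "build_report", "format_report"]

_CORRECTIONS = {
    "bonferroni": bonferroni_decisions,
    "holm": holm_decisions,
    "simes": simes_decisions,
}


@dataclass(frozen=True)
class PosthocReport:
    """All cell statistics for one table.

    ``cells`` has one row per cell keyed by (row label, col label), sorted by
    descending squared adjusted residual, with signed residuals, asymptotic
    p-values, the exact p-value, and one boolean significance column per
    requested correction method.
    """

    table: ContingencyTable
    overall: ChiSquaredResult
    cells: pd.DataFrame
    decisions: dict[str, MultiplicityDecision]
    alpha: float


def build_report(
    table: ContingencyTable,
    alpha: float = 0.05,
    corrections: tuple[str, ...] = ("simes",),
) -> PosthocReport:
    """Run the full post-hoc analysis on a table.

    Multiplicity decisions are made on the exact p-values (per correction
    method); asymptotic decisions can be derived from the p_adj column.
    """
    overall = chi_squared_test(table)
    res = residual_matrices(table)
    p_exact = exact_pvalue_matrix(table)
    R, C = table.shape
    rows = []
    for i in range(R):
        for j in range(C):
            rows.append(
                {
                    "row": table.row_labels[i],
                    "col": table.col_labels[j],
                    "count": int(table.counts[i, j]),
                    "raw": res["raw"][i, j],
                    "std": res["std"][i, j],
                    "adj": res["adj"][i, j],
                    "raw_sq": res["raw"][i, j] ** 2,
                    "std_sq": res["std"][i, j] ** 2,
                    "adj_sq": res["adj"][i, j] ** 2,
                    "p_std": res["p_std"][i, j],
                    "p_adj": res["p_adj"][i, j],
                    "p_exact": p_exact[i, j],
                }
            )
    frame = pd.DataFrame(rows)
    decisions: dict[str, MultiplicityDecision] = {}
    for name in corrections:
        if name not in _CORRECTIONS:
            raise ValueError(f"unknown correction {name!r}")
        dec = _CORRECTIONS[name](frame["p_exact"].to_numpy(), alpha)
        decisions[name] = dec
        frame[f"sig_{name}"] = dec.flags
    frame = frame.sort_values("adj_sq", ascending=False, kind="stable").reset_index(
        drop=True
    )
    return PosthocReport(
        table=table, overall=overall, cells=frame, decisions=decisions, alpha=alpha
    )


def _fmt_p(p: float) -> str:
    return f"{p:.2e}"


def format_report(
    report: PosthocReport, signed: bool = False, full_precision: bool = False
) -> str:
    """Human-readable report; squared statistics by default (``signed`` for
    the signed residuals), p-values in 3-significant-figure scientific
    notation unless ``full_precision``."""
    o = report.overall
    lines = [
        f"Overall chi-squared test: statistic = {o.statistic:.2f}, "
        f"df = {o.df}, p = {_fmt_p(o.p_value)}",
        f"Cell-wise post-hoc tests at alpha = {report.alpha}"
        f" ({', '.join(report.decisions)} correction on exact p-values)",
        "",
    ]
    stat_cols = ["raw", "std", "adj"] if signed else ["raw_sq", "std_sq", "adj_sq"]
    cols = ["row", "col", "count"] + stat_cols + ["p_std", "p_adj", "p_exact"]
    cols += [c for c in report.cells.columns if c.startswith("sig_")]
    df = report.cells[cols].copy()
    for c in stat_cols:
        df[c] = df[c].map(lambda v: f"{v:.2f}")
    for c in ("p_std", "p_adj", "p_exact"):
        df[c] = df[c].map(lambda v: f"{v:.17g}" if full_precision else _fmt_p(v))
    lines.append(df.to_string(index=False))
    return "\n".join(lines) + "\n"
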