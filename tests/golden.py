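"""Reference values for the two embedded example tables, frozen as printed
(statistics to 2 decimals, p-values to 3 significant figures), plus a
half-unit-in-the-last-place tolerance helper and independent oracles."""

from __future__ import annotations

from fractions import Fraction
from math import comb


def printed(s: str) -> tuple[float, float]:
    """Parse a printed number; return (value, half-ULP tolerance)."""
    s = s.strip().lower()
    if "e" in s:
        mant, exp = s.split("e")
        digits = len(mant.split(".")[1]) if "." in mant else 0
        tol = 0.5 * 10 ** (int(exp) - digits)
    else:
        digits = len(s.split(".")[1]) if "." in s else 0
        tol = 0.5 * 10**-digits
    return float(s), tol * 1.000001


# Melanoma 4x3 reference: (type row, site col) -> columns
#   freq, raw_sq, std_sq, p_std, adj_sq, p_adj, p_exact
# The (H, Head and neck) adjusted p is a deep-tail value; 59.9342 -> 9.81e-15,
# cross-checked against R's pnorm.
MELANOMA_CELLS = {
    ("H", "Head and neck"): ("22", "263.09", "45.52", "1.51e-11", "59.93", "9.81e-15", "5.62e-11"),
    ("S", "Head and neck"): ("16", "238.70", "7.59", "5.87e-3", "17.01", "3.71e-5", "4.91e-5"),
    ("H", "Extremities"): ("10", "84.82", "4.42", "3.56e-2", "11.09", "8.66e-4", "1.03e-3"),
    ("H", "Trunk"): ("2", "49.14", "5.45", "1.95e-2", "8.11", "4.40e-3", "3.62e-3"),
    ("S", "Extremities"): ("115", "109.73", "1.05", "3.06e-1", "4.49", "3.41e-2", "4.29e-2"),
    ("S", "Trunk"): ("54", "24.75", "0.50", "4.77e-1", "1.28", "2.58e-1", "3.07e-1"),
    ("I", "Extremities"): ("28", "13.25", "0.42", "5.18e-1", "1.12", "2.90e-1", "3.11e-1"),
    ("I", "Trunk"): ("17", "4.67", "0.31", "5.75e-1", "0.50", "4.81e-1", "5.14e-1"),
    ("N", "Head and neck"): ("19", "5.06", "0.24", "6.25e-1", "0.42", "5.18e-1", "5.68e-1"),
    ("N", "Extremities"): ("73", "5.64", "0.08", "7.77e-1", "0.27", "6.05e-1", "6.64e-1"),
    ("I", "Head and neck"): ("11", "2.19", "0.23", "6.31e-1", "0.32", "5.70e-1", "7.02e-1"),
    ("N", "Trunk"): ("33", "0.02", "0.00", "9.83e-1", "0.00", "9.76e-1", "1.00"),
}

# Cells significant under Simes at alpha = 0.05, per p-value column.
MELANOMA_SIG_EXACT = {
    ("H", "Head and neck"), ("S", "Head and neck"),
    ("H", "Extremities"), ("H", "Trunk"),
}
MELANOMA_SIG_ADJ = MELANOMA_SIG_EXACT

# Zebra-mussel 2x4 reference.  Shared-within-column values keyed by activity:
#   raw_sq, adj_sq, p_adj, p_exact  (identical for both awareness levels)
ZEBRA_COLUMNS = {
    "Pleasure": ("251.47", "20.61", "5.62e-06", "7.69e-06"),
    "Jet Ski": ("65.41", "13.41", "2.50e-04", "3.11e-04"),
    "Other": ("24.24", "7.09", "7.74e-03", "1.26e-02"),
    "Angler": ("8.10", "1.26", "2.62e-01", "3.25e-01"),
}
# Standardized residuals differ within a column; keyed by (activity, count)
# because the published awareness annotations are not reliable for every
# activity, while the frequency identifies the cell (both Angler cells hold
# 15, but their values are listed under their correct awareness levels).
ZEBRA_STD = {
    ("Pleasure", 68): ("3.00", "0.08"),
    ("Pleasure", 139): ("2.04", "0.15"),
    ("Jet Ski", 5): ("5.00", "0.03"),
    ("Jet Ski", 17): ("7.34", "0.01"),
    ("Other", 4): ("2.72", "0.10"),
    ("Other", 11): ("3.99", "0.05"),
}
# Both Angler cells hold 15, so they are keyed by awareness level instead.
ZEBRA_STD_ANGLER = {"Yes": ("0.45", "0.50"), "No": ("0.67", "0.41")}

ZEBRA_SIG_ACTIVITIES = {"Pleasure", "Jet Ski", "Other"}  # Angler retained


def exact_pvalue_oracle(m: int, n: int, total: int, x: int) -> Fraction:
    """Deviation-ordered exact p-value by big-integer rational enumeration.

    Independent of the package's log-space path: binomial coefficients via
    math.comb, summed as exact Fractions.
    """
    lo, hi = max(0, m + n - total), min(m, n)
    obs = abs(x * total - m * n)
    num = sum(
        comb(m, k) * comb(total - m, n - k)
        for k in range(lo, hi + 1)
        if abs(k * total - m * n) >= obs
    )
    return Fraction(num, comb(total, n))


def enumerate_tables(row_margins, col_margins):
    """All non-negative integer matrices with the given margins (tiny N only)."""
    R, C = len(row_margins), len(col_margins)

    def rows(remaining_cols, i):
        if i == R - 1:
            if min(remaining_cols) >= 0 and sum(remaining_cols) == row_margins[i]:
                yield [list(remaining_cols)]
            return
        for row in compositions(row_margins[i], remaining_cols):
            rest = [a - b for a, b in zip(remaining_cols, row)]
            for tail in rows(rest, i + 1):
                yield [row] + tail

    def compositions(total, caps):
        if len(caps) == 1:
            if 0 <= total <= caps[0]:
                yield [total]
            return
        for v in range(0, min(total, caps[0]) + 1):
            for rest in compositions(total - v, caps[1:]):
                yield [v] + rest

    yield from rows(list(col_margins), 0)


def table_probability(counts, row_margins, col_margins, total) -> Fraction:
    """Multiple-hypergeometric probability of a full R x C table (exact)."""
    from math import factorial

    num = 1
    for m in row_margins:
        num *= factorial(m)
    for n in col_margins:
        num *= factorial(n)
    den = factorial(total)
    for row in counts:
        for v in row:
            den *= factorial(v)
    return Fraction(num, den)
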