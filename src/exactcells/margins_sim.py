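"""Fixed-margin null-table simulation and the Monte-Carlo FWER harness.

The study design: draw random positive row/column margins for a given table
size and total N, then draw null tables from the multiple-hypergeometric
distribution of independence conditioned on those margins.  For every table
the all-cell p-values are computed twice — asymptotically from the adjusted
residual and exactly by hypergeometric enumeration — Simes thresholds
alpha*k/W are applied, and the family-wise error rate (FWER) of each method
is the fraction of tables with at least one rejected cell.  Because every
table is drawn from the independence null, any rejection is a false one.

Margin generation uses independent uniform multinomial allocation with a
positivity redraw; it is a pluggable strategy (``margin_sampler``) because
the exact method's validity is conditional on margins and therefore does
not depend on this choice, while the asymptotic method's inflation is a
property of the tables themselves.

Fixed-margin tables are drawn by sequential row filling: each row is a
multivariate-hypergeometric draw from the remaining column totals, which is
distributionally identical to Patefield's classical sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.special import ndtr

from .exact_posthoc import exact_pvalue_lookup
from .table_core import ContingencyTable

__all__ = [
    "SimConfig",
    "FwerEstimate",
    "GammaComparison",
    "GAMMA_CATEGORIES",
    "sample_margins",
    "sample_table_fixed_margins",
    "estimate_fwer",
    "compare_methods",
    "make_fixture",
]

# Reference tables used throughout the examples and tests:
# a 2 x 4 boater-activity x zebra-mussel-awareness survey (N = 274) and a
# 4 x 3 melanoma tumor-type x tumor-site cross-classification (N = 400).
ZEBRA_MUSSEL_COUNTS = np.array([[139, 15, 5, 4], [68, 15, 17, 11]])
ZEBRA_MUSSEL_ROWS = ("Yes", "No")
ZEBRA_MUSSEL_COLS = ("Pleasure", "Angler", "Jet Ski", "Other")

MELANOMA_COUNTS = np.array(
    [[10, 22, 2], [28, 11, 17], [73, 19, 33], [115, 16, 54]]
)
MELANOMA_ROWS = ("H", "I", "N", "S")
MELANOMA_COLS = ("Extremities", "Head and neck", "Trunk")


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo design: table size, total, scale, level and seed.

    The default scale (200 margin sets x 200 tables each) keeps a sweep over
    several configurations in the minutes range; ``full_scale()`` returns the
    1,000 x 2,000 design of a full study run.
    """

    R: int
    C: int
    N: int
    n_margin_sets: int = 200
    n_tables_per_margin: int = 200
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R < 2 or self.C < 2:
            raise ValueError("table must be at least 2 x 2")
        if self.N < max(self.R, self.C):
            raise ValueError(
                f"N={self.N} cannot give positive margins for {self.R}x{self.C}"
            )
        if self.n_margin_sets < 1 or self.n_tables_per_margin < 1:
            raise ValueError("simulation sizes must be positive")
        if not (0 <= self.alpha < 1):
            raise ValueError("alpha must lie in [0, 1)")

    def full_scale(self) -> "SimConfig":
        return replace(self, n_margin_sets=1000, n_tables_per_margin=2000)

    @property
    def n_tables(self) -> int:
        return self.n_margin_sets * self.n_tables_per_margin


@dataclass(frozen=True)
class FwerEstimate:
    """Monte-Carlo FWER of both methods under the null design.

    ``mc_stderr`` is the binomial standard error of the exact-method
    estimate; ``n_effective`` the number of simulated tables.
    """

    fwer_asymptotic: float
    fwer_exact: float
    mc_stderr: float
    n_effective: int


GAMMA_CATEGORIES = (
    "asy_eq_exact_pos",   # Gamma_Asy = Gamma_Exact > 0
    "asy_gt_exact_zero",  # Gamma_Asy > Gamma_Exact = 0
    "asy_gt_exact_pos",   # Gamma_Asy > Gamma_Exact > 0
    "exact_gt_asy_zero",  # Gamma_Exact > Gamma_Asy = 0
    "exact_gt_asy_pos",   # Gamma_Exact > Gamma_Asy > 0
)

GAMMA_LABELS = {
    "asy_eq_exact_pos": "Gamma_Asy = Gamma_Exact > 0",
    "asy_gt_exact_zero": "Gamma_Asy > Gamma_Exact = 0",
    "asy_gt_exact_pos": "Gamma_Asy > Gamma_Exact > 0",
    "exact_gt_asy_zero": "Gamma_Exact > Gamma_Asy = 0",
    "exact_gt_asy_pos": "Gamma_Exact > Gamma_Asy > 0",
}


@dataclass(frozen=True)
class GammaComparison:
    """Counts of simulated tables per disagreement category.

    Gamma_Asy / Gamma_Exact are the numbers of cells each method flags under
    Simes; tables with no flagged cell by either method are excluded.
    """

    counts: dict[str, int]
    total: int

    @property
    def proportions(self) -> dict[str, float]:
        """Percentages over the included cases (sum to 100 when total > 0)."""
        if self.total == 0:
            return {k: 0.0 for k in GAMMA_CATEGORIES}
        return {k: 100.0 * self.counts[k] / self.total for k in GAMMA_CATEGORIES}


def sample_margins(
    N: int, R: int, C: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random positive margins summing to N: uniform multinomial allocation
    over the R rows and (independently) the C columns, redrawn until every
    margin is at least 1."""
    if N < max(R, C):
        raise ValueError(f"N={N} too small for positive margins of {R} rows / {C} cols")

    def draw(k: int) -> np.ndarray:
        while True:
            v = rng.multinomial(N, np.full(k, 1.0 / k))
            if (v > 0).all():
                return v.astype(np.int64)

    return draw(R), draw(C)


def _sample_counts(
    row_margins: np.ndarray, col_margins: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One null table with the given margins; sequential multivariate-
    hypergeometric row filling (distribution identical to Patefield)."""
    R = row_margins.size
    remaining = np.asarray(col_margins, dtype=np.int64).copy()
    out = np.empty((R, remaining.size), dtype=np.int64)
    for i in range(R - 1):
        out[i] = rng.multivariate_hypergeometric(remaining, int(row_margins[i]))
        remaining -= out[i]
    out[R - 1] = remaining
    return out


def sample_table_fixed_margins(
    row_margins, col_margins, rng: np.random.Generator
) -> ContingencyTable:
    """Draw one table from the conditional null of independence given margins."""
    rm = np.asarray(row_margins, dtype=np.int64)
    cm = np.asarray(col_margins, dtype=np.int64)
    if rm.sum() != cm.sum():
        raise ValueError(
            f"margin totals differ: rows sum to {rm.sum()}, columns to {cm.sum()}"
        )
    if (rm < 0).any() or (cm < 0).any():
        raise ValueError("margins must be non-negative")
    return ContingencyTable(_sample_counts(rm, cm, rng))


def _simes_reject_count(p_flat: np.ndarray, alpha: float) -> int:
    """Number of hypotheses rejected by the Simes step-up rule at level alpha."""
    if alpha <= 0:
        return 0
    sp = np.sort(p_flat)
    W = sp.size
    ok = sp <= alpha * np.arange(1, W + 1) / W
    if not ok.any():
        return 0
    cutoff = sp[np.nonzero(ok)[0][-1]]
    return int(np.searchsorted(sp, cutoff, side="right"))


def _simulate_rejections(
    config: SimConfig,
    margin_sampler: Callable = sample_margins,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-table Simes rejection counts (asymptotic, exact) under the null."""
    rng = np.random.default_rng(config.seed)
    R, C, N, alpha = config.R, config.C, config.N, config.alpha
    n_asy = np.empty(config.n_tables, dtype=np.int64)
    n_ex = np.empty(config.n_tables, dtype=np.int64)
    t = 0
    for _ in range(config.n_margin_sets):
        rm, cm = margin_sampler(N, R, C, rng)
        e = np.outer(rm, cm) / N
        inv_se = 1.0 / np.sqrt(e * (1 - rm / N)[:, None] * (1 - cm / N)[None, :])
        # exact p-value lookup per (row margin, column margin) pair
        lookups = [[exact_pvalue_lookup(int(m), int(n), N) for n in cm] for m in rm]
        for _ in range(config.n_tables_per_margin):
            x = _sample_counts(rm, cm, rng)
            adj = (x - e) * inv_se
            p_asy = 2.0 * ndtr(-np.abs(adj))
            p_ex = np.empty(R * C)
            k = 0
            for i in range(R):
                row = x[i]
                lrow = lookups[i]
                for j in range(C):
                    lo, pvec = lrow[j]
                    p_ex[k] = pvec[row[j] - lo]
                    k += 1
            n_asy[t] = _simes_reject_count(p_asy.ravel(), alpha)
            n_ex[t] = _simes_reject_count(p_ex, alpha)
            t += 1
    return n_asy, n_ex


def estimate_fwer(
    config: SimConfig, margin_sampler: Callable = sample_margins
) -> FwerEstimate:
    """Monte-Carlo FWER of the asymptotic and exact cell tests with Simes
    correction: the fraction of simulated null tables with >= 1 rejection."""
    n_asy, n_ex = _simulate_rejections(config, margin_sampler)
    n = n_asy.size
    f_asy = float((n_asy > 0).mean())
    f_ex = float((n_ex > 0).mean())
    se = float(np.sqrt(f_ex * (1 - f_ex) / n))
    return FwerEstimate(
        fwer_asymptotic=f_asy, fwer_exact=f_ex, mc_stderr=se, n_effective=n
    )


def compare_methods(
    config: SimConfig, margin_sampler: Callable = sample_margins
) -> GammaComparison:
    """Classify each simulated table by how the two methods' rejection counts
    compare; tables with no rejection by either method are excluded."""
    n_asy, n_ex = _simulate_rejections(config, margin_sampler)
    include = (n_asy > 0) | (n_ex > 0)
    a, ex = n_asy[include], n_ex[include]
    counts = {
        "asy_eq_exact_pos": int(((a == ex) & (ex > 0)).sum()),
        "asy_gt_exact_zero": int(((a > ex) & (ex == 0)).sum()),
        "asy_gt_exact_pos": int(((a > ex) & (ex > 0)).sum()),
        "exact_gt_asy_zero": int(((ex > a) & (a == 0)).sum()),
        "exact_gt_asy_pos": int(((ex > a) & (a > 0)).sum()),
    }
    return GammaComparison(counts=counts, total=int(include.sum()))


def make_fixture(
    name: str, rng: np.random.Generator | None = None
) -> ContingencyTable:
    """Embedded reference tables and a random-table generator.

    ``zebra_mussel``: the 2 x 4 awareness survey (N = 274).
    ``melanoma``: the 4 x 3 tumor type x site table (N = 400).
    ``random``: a table with random shape (2-6 rows/cols) and positive
    margins, drawn from the given generator (for property tests).
    """
    if name == "zebra_mussel":
        return ContingencyTable(ZEBRA_MUSSEL_COUNTS, ZEBRA_MUSSEL_ROWS, ZEBRA_MUSSEL_COLS)
    if name == "melanoma":
        return ContingencyTable(MELANOMA_COUNTS, MELANOMA_ROWS, MELANOMA_COLS)
    if name == "random":
        if rng is None:
            raise ValueError("random fixture needs an rng")
        R = int(rng.integers(2, 7))
        C = int(rng.integers(2, 7))
        N = int(rng.integers(max(R, C) * 2, 201))
        rm, cm = sample_margins(N, R, C, rng)
        return sample_table_fixed_margins(rm, cm, rng)
    raise ValueError(f"unknown fixture {name!r}")
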