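"""Family-wise error control across the W = R*C cell tests.

Three rules are provided, in increasing power:

* Bonferroni — reject p <= alpha / W.
* Holm — step-down: the k-th smallest p-value is compared with
  alpha / (W + 1 - k).
* Simes — step-up: find the largest rank k with p_(k) <= alpha k / W and
  reject every hypothesis with p-value <= p_(k).

Cells with identical p-values always receive one joint decision: the tie
group is evaluated at the largest adjusted p-value (equivalently the largest
rank) within the group.  Boundary comparisons use <=, i.e. a p-value exactly
equal to its threshold is rejected.

Rejection sets nest: bonferroni ⊆ holm ⊆ simes for any p-value vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MultiplicityDecision",
    "bonferroni_decisions",
    "holm_decisions",
    "simes_decisions",
]


@dataclass(frozen=True)
class MultiplicityDecision:
    """Per-hypothesis reject/retain flags under one correction rule.

    ``flags`` has the same shape as the input p-values; ``thresholds`` are
    the per-rank cutoffs of the rule; ``adjusted`` are multiplicity-adjusted
    p-values (tie groups share their largest adjusted value), so that
    ``flags == (adjusted <= alpha)``.
    """

    method: str
    alpha: float
    flags: np.ndarray
    thresholds: np.ndarray
    adjusted: np.ndarray


def _validate(pvalues, alpha: float) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        bad = p[np.isnan(p) | (p < 0) | (p > 1)][0]
        raise ValueError(f"p-values must lie in [0, 1], got {bad}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return p


def _tie_max(sorted_p: np.ndarray, adjusted: np.ndarray) -> np.ndarray:
    """Give every member of a tie group the group's largest adjusted value."""
    out = adjusted.copy()
    start = 0
    for k in range(1, sorted_p.size + 1):
        if k == sorted_p.size or sorted_p[k] != sorted_p[start]:
            out[start:k] = adjusted[start:k].max()
            start = k
    return out


def bonferroni_decisions(pvalues, alpha: float) -> MultiplicityDecision:
    """Reject every p-value at or below alpha / W."""
    p = _validate(pvalues, alpha)
    W = p.size
    adjusted = np.minimum(p * W, 1.0)
    return MultiplicityDecision(
        method="bonferroni",
        alpha=alpha,
        flags=adjusted <= alpha,
        thresholds=np.array([alpha / W]),
        adjusted=adjusted,
    )


def holm_decisions(pvalues, alpha: float) -> MultiplicityDecision:
    """Holm step-down: rank k is tested against alpha / (W + 1 - k).

    Implemented through adjusted p-values max_{j<=k} (W + 1 - j) p_(j)
    (capped at 1), with tied p-values sharing the largest adjusted value so
    that a tie group is decided jointly at its largest rank.
    """
    p = _validate(pvalues, alpha)
    W = p.size
    flat = p.ravel()
    order = np.argsort(flat, kind="stable")
    sp = flat[order]
    mult = W - np.arange(W)  # W + 1 - k for k = 1..W
    adj_sorted = np.minimum(np.maximum.accumulate(mult * sp), 1.0)
    adj_sorted = _tie_max(sp, adj_sorted)
    adjusted = np.empty(W)
    adjusted[order] = adj_sorted
    adjusted = adjusted.reshape(p.shape)
    return MultiplicityDecision(
        method="holm",
        alpha=alpha,
        flags=adjusted <= alpha,
        thresholds=alpha / mult,
        adjusted=adjusted,
    )


def simes_decisions(pvalues, alpha: float) -> MultiplicityDecision:
    """Simes step-up: reject all p <= p_(k*) where k* is the largest rank
    with p_(k) <= alpha k / W; if no rank qualifies, reject nothing.

    The reported adjusted p-values are min_{j >= k} W p_(j) / j capped at 1,
    with tie groups sharing their largest value; the flags equal the step-up
    decisions (rejecting by p-value cutoff makes tied cells agree by
    construction).
    """
    p = _validate(pvalues, alpha)
    W = p.size
    flat = p.ravel()
    order = np.argsort(flat, kind="stable")
    sp = flat[order]
    ranks = np.arange(1, W + 1)
    thresholds = alpha * ranks / W
    passing = sp <= thresholds
    if passing.any():
        cutoff = sp[np.nonzero(passing)[0][-1]]
        flags = p <= cutoff
    else:
        flags = np.zeros_like(p, dtype=bool)
    adj_sorted = np.minimum(np.minimum.accumulate((W * sp / ranks)[::-1])[::-1], 1.0)
    adj_sorted = _tie_max(sp, adj_sorted)
    adjusted = np.empty(W)
    adjusted[order] = adj_sorted
    adjusted = adjusted.reshape(p.shape)
    return MultiplicityDecision(
        method="simes",
        alpha=alpha,
        flags=flags,
        thresholds=thresholds,
        adjusted=adjusted,
    )
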