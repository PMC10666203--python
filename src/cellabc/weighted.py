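"""Weighted-sample utilities shared across the engine and diagnostics.

One quantile convention is used everywhere: type 1 (no interpolation), i.e.
the smallest sample value whose cumulative (weighted) probability reaches the
requested level. The epsilon schedule, credible intervals and report tables
all go through these functions so they cannot drift apart.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "type1_quantile",
    "weighted_quantile",
    "ess",
    "weighted_ecdf",
    "weighted_ks_statistic",
    "weighted_ks_test",
]


def type1_quantile(values, q: float) -> float:
    """Lower empirical quantile: smallest value with cdf >= q."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("quantile of empty sequence")
    if not 0.0 < q <= 1.0:
        raise ValueError(f"quantile level must be in (0, 1], got {q}")
    idx = int(np.ceil(q * v.size)) - 1
    return float(v[max(idx, 0)])


def weighted_quantile(values, weights, q: float) -> float:
    """Smallest sample value whose cumulative weight reaches ``q``.

    Weights need not be normalized; they are normalized internally.
    Reduces to :func:`type1_quantile` for equal weights.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be 1-D and equal length")
    if np.any(w < 0):
        raise ValueError("negative weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order]) / total
    # guard against cumulative rounding never reaching 1.0 exactly
    cw[-1] = 1.0
    idx = int(np.searchsorted(cw, q - 1e-12, side="left"))
    return float(v[order][min(idx, v.size - 1)])


def ess(weights) -> float:
    """Effective sample size 1 / sum(w_i^2) of a normalized weight vector."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"weights must be normalized, sum={w.sum()!r}")
    return float(1.0 / np.sum(w**2))


def weighted_ecdf(values, weights):
    """Return (sorted unique support, cdf values) of a weighted sample."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w) / w.sum()
    return v, cw


def weighted_ks_statistic(x1, w1, x2, w2) -> float:
    """Sup-distance between two weighted empirical cdfs."""
    v1, c1 = weighted_ecdf(x1, w1)
    v2, c2 = weighted_ecdf(x2, w2)
    grid = np.concatenate([v1, v2])
    f1 = np.concatenate([[0.0], c1])[np.searchsorted(v1, grid, side="right")]
    f2 = np.concatenate([[0.0], c2])[np.searchsorted(v2, grid, side="right")]
    return float(np.max(np.abs(f1 - f2)))


def weighted_ks_test(x1, w1, x2, w2, alpha: float = 0.01):
    """Two-sample KS test for weighted samples.

    The effective sample size of each weighted sample replaces the raw count
    in the classical asymptotic critical value
    ``c(alpha) * sqrt((n1 + n2) / (n1 * n2))`` with
    ``c(alpha) = sqrt(-ln(alpha / 2) / 2)``.

    Returns (statistic, critical_value, reject).
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    n1 = ess(w1 / w1.sum())
    n2 = ess(w2 / w2.sum())
    d = weighted_ks_statistic(x1, w1, x2, w2)
    c_alpha = np.sqrt(-np.log(alpha / 2.0) / 2.0)
    crit = float(c_alpha * np.sqrt((n1 + n2) / (n1 * n2)))
    return d, crit, d > crit
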