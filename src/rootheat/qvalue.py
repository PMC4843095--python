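"""Storey q-values with smoother-based pi0 estimation.

q(p) estimates the false discovery rate incurred by calling everything at or
below p.  The null proportion pi0 is estimated from the flat right tail of
the p-value histogram over a lambda grid (0, 0.05, ..., 0.90) with a cubic
smoother evaluated at the grid's right end, then clipped to (0, 1].  For
small families (< 100 tests) the estimate is unstable and pi0 = 1 is used,
which reduces q-values to Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import numpy as np

__all__ = ["estimate_pi0", "storey_qvalues"]

_LAMBDA_GRID = np.arange(0.0, 0.9001, 0.05)
_MIN_TESTS_FOR_PI0 = 100


def estimate_pi0(p_values, lambdas=_LAMBDA_GRID) -> float:
    """Smoother estimate of the proportion of true null hypotheses."""
    p = np.asarray(p_values, float)
    m = p.size
    if m < _MIN_TESTS_FOR_PI0:
        return 1.0
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    # cubic polynomial smoother across the grid, read off at the right end
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """q-values for a family of p-values; monotone in p and bounded by 1.

    With ``pi0`` forced to 1 this is exactly the Benjamini-Hochberg
    step-up adjustment.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
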