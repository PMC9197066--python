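"""Cauchy-combination (ACAT) machinery.

A set of p-values p_1..p_d with non-negative weights ω is combined through

    T = Σ_k ω_k tan((0.5 − p_k) π) / Σ_k ω_k,
    p = P(Cauchy > T) = 0.5 − arctan(T)/π.

The transform is exact under independence and remarkably robust under
arbitrary dependence because the Cauchy tail is dominated by the single
smallest p-value. Numerical care is needed at both ends: tan() overflows
for p near 0 (replaced by the asymptote 1/(pπ)) and p = 1 maps to the
lower Cauchy tail (perturbed to 1 − 1/d so a vector of uninformative
tests cannot force the combined p to 1 exactly).
"""

from __future__ import annotations

import numpy as np

_TINY_P = 1e-15
_P_FLOOR = 1e-308  # below this the tan() asymptote term overflows


def cauchy_sf(t: float) -> float:
    """Upper-tail standard Cauchy probability, accurate in both tails."""
    if t > 1.0:
        return float(np.arctan(1.0 / t) / np.pi)
    if t < -1.0:
        return float(1.0 - np.arctan(-1.0 / t) / np.pi)
    return float(0.5 - np.arctan(t) / np.pi)


def acat_combine(pvals, weights=None) -> float:
    """Combine p-values by the weighted Cauchy transform.

    Parameters
    ----------
    pvals : array-like of p-values in (0, 1].
    weights : optional non-negative weights, default equal. Not required
        to sum to one.

    Returns
    -------
    Combined p-value in (0, 1].
    """
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("acat_combine requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        if w.shape != p.shape:
            raise ValueError("weights length mismatch")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 and not all zero")
    w = w / w.sum()

    d = p.size
    p = np.where(p == 1.0, 1.0 - 1.0 / d, p)
    p = np.maximum(p, _P_FLOOR)

    small = p < _TINY_P
    terms = np.empty_like(p)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    # tan((0.5 - p)π) ~ 1/(pπ) as p → 0
    terms[small] = 1.0 / (p[small] * np.pi)
    t = float(np.dot(w, terms))
    if not np.isfinite(t):
        raise ValueError("non-finite Cauchy statistic")
    out = cauchy_sf(t)
    return min(max(out, 5e-324), 1.0)
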