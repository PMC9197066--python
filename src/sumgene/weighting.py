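"""MAF-based variant weights and their combination with causal probabilities.

Rare-variant tests up-weight low-frequency variants through a beta density
evaluated at the minor-allele frequency, ``w_k = f_Beta(maf_k; a1, a2)``.
The conventional choices are Beta(1, 25) (strong rare-variant up-weighting)
and Beta(1, 1) (flat). A per-variant probability of being causal, when
available from functional annotation, multiplies the beta weight.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import EffectiveWeights


def beta_weights(maf: np.ndarray, a1: float, a2: float) -> np.ndarray:
    """Beta-density weights evaluated at the minor-allele frequency.

    Parameters
    ----------
    maf : array of MAFs in (0, 0.5].
    a1, a2 : strictly positive beta-distribution shape parameters.
    """
    maf = np.asarray(maf, dtype=float)
    if a1 <= 0 or a2 <= 0:
        raise ValueError("beta parameters must be strictly positive")
    if maf.size and (maf.min() <= 0 or maf.max() > 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    return stats.beta.pdf(maf, a1, a2)


class ZeroWeightsError(ValueError):
    """All effective weights vanished; the grid cell carries no information."""


def effective_weights(
    w_beta: np.ndarray,
    probs_channel: np.ndarray | None = None,
    i: int = 1,
    j: int = 0,
) -> EffectiveWeights:
    """Combine beta weights with one annotation channel's probabilities.

    j=0 means "no annotation": the beta weights pass through unchanged.
    For j >= 1 the probabilities enter multiplicatively on the weight
    scale, ``w_k = w_beta_k * prob_k``.
    """
    w_beta = np.asarray(w_beta, dtype=float)
    if (j == 0) != (probs_channel is None):
        raise ValueError("j=0 if and only if probabilities are absent")
    if probs_channel is None:
        w = w_beta.copy()
    else:
        probs = np.asarray(probs_channel, dtype=float)
        if probs.shape != w_beta.shape:
            raise ValueError("probability vector length mismatch")
        if probs.size and (probs.min() < 0 or probs.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        w = w_beta * probs
    if not np.any(w > 0):
        raise ZeroWeightsError("all effective weights are zero")
    return EffectiveWeights(w=w, i=i, j=j)
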