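"""Hill-number diversity and the multiplicative beta-partition.

The Hill number of order q is the effective number of equally abundant
taxa:

    qD = (sum_i p_i^q)^(1/(1-q))        for q != 1
    1D = exp(-sum_i p_i ln p_i)          (the q -> 1 limit)

q = 0 is richness, q = 1 the Shannon exponential, q = 2 inverse Simpson.
Beta-diversity between replicate communities is partitioned
multiplicatively and expressed as the beta-partition

    beta = 1 - alpha_bar / gamma

where alpha_bar is the mean within-replicate qD and gamma the qD of the
pooled community.  beta is 0 for identical replicates and approaches
1 - 1/n for n fully distinct, equally rich replicates at q = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

__all__ = ["hill_diversity", "beta_partition", "bray_curtis", "BetaPartition"]

_Q1_TOL = 1e-9


def hill_diversity(counts, q: float) -> float:
    """Hill number of order ``q`` for one community (zero counts ignored)."""
    if q < 0:
        raise ValueError("Hill order q must be >= 0")
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("community has no individuals")
    p = c[c > 0] / total
    if q == 0:
        return float(p.size)
    if abs(q - 1.0) < _Q1_TOL:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


@dataclass
class BetaPartition:
    """Multiplicative alpha/gamma partition of a replicate group."""

    q: float
    alpha_bar: float
    gamma: float
    beta: float


def beta_partition(group_samples, q: float = 0.0) -> BetaPartition:
    """Beta-partition (1 - alpha_bar/gamma) over >= 2 replicate count vectors."""
    vectors = [np.asarray(v) for v in group_samples]
    if len(vectors) < 2:
        raise ValueError("beta-partition needs at least 2 samples")
    alphas = [hill_diversity(v, q) for v in vectors]
    gamma = hill_diversity(np.sum(vectors, axis=0), q)
    alpha_bar = float(np.mean(alphas))
    return BetaPartition(q=q, alpha_bar=alpha_bar, gamma=gamma, beta=1.0 - alpha_bar / gamma)


def bray_curtis(x, y, transform: str = "sqrt_relative") -> float:
    """Bray-Curtis dissimilarity between two count vectors.

    ``transform="sqrt_relative"`` (default) takes the square root of
    relative abundances first; ``"none"`` uses raw counts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("vectors must have positive totals")
    if transform == "sqrt_relative":
        x = np.sqrt(x / x.sum())
        y = np.sqrt(y / y.sum())
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return float(_scipy_braycurtis(x, y))
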