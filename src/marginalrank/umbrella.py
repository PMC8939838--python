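"""The Neyman-Pearson umbrella algorithm.

Given scores of left-out class-0 observations, the umbrella algorithm picks
the threshold of a scoring-type classifier as an order statistic T_(k*) such
that the resulting classifier's type I error exceeds the target level alpha
with probability at most delta1.  k* is the smallest order k whose binomial
tail

    sum_{j=k}^{m2} C(m2, j) (1 - alpha)^j alpha^(m2 - j)

is at most delta1.  The rule is score-agnostic: any scoring function works,
this package uses kernel density ratios by default.

Order statistics are indexed 1-based, matching the usual order-statistic
notation T_(1) <= ... <= T_(m2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["NPThreshold", "NoValidOrderError", "min_order", "np_threshold",
           "classify_np", "minimal_m2"]


class NoValidOrderError(ValueError):
    """No finite k* exists: the left-out class-0 sample is too small.

    Carries ``minimal_m2``, the smallest left-out class-0 size for which a
    finite order exists at the requested (alpha, delta1).
    """

    def __init__(self, m2: int, alpha: float, delta1: float):
        self.minimal_m2 = minimal_m2(alpha, delta1)
        super().__init__(
            f"no valid order for m2={m2}, alpha={alpha}, delta1={delta1}: "
            f"(1-alpha)^m2 > delta1; need m2 >= {self.minimal_m2}"
        )


@dataclass(frozen=True)
class NPThreshold:
    """An umbrella threshold: the k*-th smallest left-out class-0 score."""

    k_star: int        # 1-based order
    threshold: float
    m2: int
    alpha: float
    delta1: float


def minimal_m2(alpha: float, delta1: float) -> int:
    """Smallest m2 admitting a finite k*: ceil(log delta1 / log(1 - alpha))."""
    return int(math.ceil(math.log(delta1) / math.log1p(-alpha)))


def min_order(m2: int, alpha: float, delta1: float) -> int:
    """Minimal 1-based order k* with binomial tail <= delta1.

    The tail sum_{j=k}^{m2} C(m2,j)(1-alpha)^j alpha^(m2-j) equals
    P(Bin(m2, 1-alpha) >= k) and is evaluated through the regularised
    incomplete beta function (scipy's survival function), which is stable
    for m2 in the thousands.
    """
    if not (0.0 < alpha < 1.0 and 0.0 < delta1 < 1.0):
        raise ValueError("alpha and delta1 must lie in (0, 1)")
    if m2 < 1:
        raise ValueError("m2 must be a positive integer")
    # existence: tail at k = m2 is (1-alpha)^m2; allow the exact boundary
    if m2 * math.log1p(-alpha) > math.log(delta1) + 1e-12:
        raise NoValidOrderError(m2, alpha, delta1)
    # P(X >= k) = sf(k - 1) for X ~ Bin(m2, 1 - alpha); decreasing in k.
    # sf carries ~1e-15 relative rounding, so boundary cases like
    # P(Bin(35,.5) >= 18) = .5 exactly need a hair of slack in "<= delta1".
    ks = np.arange(1, m2 + 1)
    tails = stats.binom.sf(ks - 1, m2, 1.0 - alpha)
    cutoff = delta1 * (1.0 + 1e-12)
    idx = int(np.searchsorted(-tails, -cutoff))
    return int(ks[min(idx, m2 - 1)])


def np_threshold(class0_scores, alpha: float, delta1: float) -> NPThreshold:
    """Umbrella threshold from left-out class-0 scores."""
    scores = np.asarray(class0_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty class-0 score vector")
    if not np.all(np.isfinite(scores)):
        raise ValueError("class-0 scores must be finite")
    m2 = scores.size
    k_star = min_order(m2, alpha, delta1)
    ordered = np.sort(scores)
    return NPThreshold(k_star=k_star, threshold=float(ordered[k_star - 1]),
                       m2=m2, alpha=alpha, delta1=delta1)


def classify_np(scores, threshold: float) -> np.ndarray:
    """NP classifier: label 1 iff score strictly exceeds the threshold."""
    return (np.asarray(scores, dtype=float) > threshold).astype(int)
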