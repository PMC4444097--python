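"""The Audic–Claverie conditional Poisson exact test for two tag libraries.

Each tag's count in a library is modelled as Poisson: the tag occupies a
tiny fraction of the library, so its count x has pmf
``p(x) = exp(-lam) lam^x / x!``.  Conditional on observing ``x`` tags in
library 1 (total clean reads ``N1``), the count ``Y`` in library 2
(total ``N2``) under the hypothesis of equal per-read rate follows

    p(Y = y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

which is a negative-binomial form with ``x + 1`` "successes" and success
probability ``N1 / (N1 + N2)``.  Everything here is evaluated in log
space with log-gamma factorials, so counts up to 10^7 are handled
without overflow.

Significance of an observed pair is measured by tail mass of the
conditional distribution, doubled for two-sidedness and capped at 1.
The larger of the two counts serves as the conditioning count; the
smaller count's tail is evaluated.  With near-equal library sizes the
smaller count sits in the lower tail, so the p-value is
``2 * P(Y <= y_small | x_large)`` — equivalently, in the y > x
orientation, twice the strict upper tail ``2 * P(Y > y | x)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .tag_io import CountPair, LibraryPair

__all__ = [
    "PoissonModel",
    "TailInterval",
    "ACResult",
    "poisson_pmf",
    "log_conditional_pmf",
    "conditional_pmf",
    "lower_tail",
    "upper_tail",
    "two_sided_p",
    "confidence_interval",
]

# Relative truncation bound for open-ended tail sums.
_TRUNCATION_EPS = 1e-16


@dataclass(frozen=True)
class PoissonModel:
    """Poisson rate for a single tag's count."""

    lam: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"Poisson rate must be positive, got {self.lam}")


@dataclass(frozen=True)
class TailInterval:
    """The [y_min, y_max] interval whose tails each hold at most epsilon.

    ``two_epsilon`` is the total excluded mass 2*eps (0.05 for the 95%
    interval, 0.01 for 99%).  ``y_min`` is None when even y = 0 carries
    more than eps of lower-tail mass.
    """

    y_min: int | None
    y_max: int | None
    two_epsilon: float

    def contains(self, y: int) -> bool:
        lo_ok = self.y_min is None or y > self.y_min
        hi_ok = self.y_max is None or y < self.y_max
        return lo_ok and hi_ok


@dataclass(frozen=True)
class ACResult:
    """Two-sided p-value with the inclusive tail masses that produced it.

    The tails are those of the tested (smaller) count under the
    distribution conditioned on the larger count.
    """

    p_value: float
    lower_tail_mass: float
    upper_tail_mass: float


def poisson_pmf(x: int, model: PoissonModel) -> float:
    """``exp(-lam) lam^x / x!`` evaluated in log space."""
    if x < 0:
        raise ValueError(f"count must be >= 0, got {x}")
    return math.exp(x * math.log(model.lam) - model.lam - math.lgamma(x + 1))


def log_conditional_pmf(y, x: int, libs: LibraryPair):
    """log p(Y=y | x) for scalar or array ``y`` (vectorized over y)."""
    if x < 0:
        raise ValueError(f"conditioning count must be >= 0, got {x}")
    y_arr = np.asarray(y)
    if np.any(y_arr < 0):
        raise ValueError("tested count must be >= 0")
    log_r = math.log(libs.n2) - math.log(libs.n1)           # log(N2/N1)
    log_1pr = math.log1p(libs.n2 / libs.n1)                 # log(1 + N2/N1)
    out = (
        y_arr * log_r
        + gammaln(x + y_arr + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y_arr + 1.0)
        - (x + y_arr + 1.0) * log_1pr
    )
    return out if out.shape else float(out)


def conditional_pmf(y, x: int, libs: LibraryPair):
    """p(Y=y | x); see :func:`log_conditional_pmf`."""
    return np.exp(log_conditional_pmf(y, x, libs))


def _conditional_mean(x: int, libs: LibraryPair) -> float:
    # Negative-binomial mean: (x+1) * N2/N1.
    return (x + 1) * libs.n2 / libs.n1


def _log_sum_range(lo: int, hi: int, x: int, libs: LibraryPair) -> float:
    """log sum of p(y|x) for y in [lo, hi], chunked to bound memory."""
    if hi < lo:
        return -math.inf
    pieces = []
    chunk = 1 << 20
    for start in range(lo, hi + 1, chunk):
        stop = min(start + chunk - 1, hi)
        ys = np.arange(start, stop + 1, dtype=np.float64)
        pieces.append(logsumexp(log_conditional_pmf(ys, x, libs)))
    return float(logsumexp(pieces)) if len(pieces) > 1 else float(pieces[0])


def _log_upper_open(y0: int, x: int, libs: LibraryPair) -> float:
    """log P(Y >= y0 | x) by direct summation with a geometric stop bound.

    The term ratio p(y+1)/p(y) = q*(x+y+1)/(y+1) with q = N2/(N1+N2)
    decreases toward q < 1, so past the mode the remainder after any
    point is bounded by a geometric series; summation extends until that
    bound is negligible relative to the accumulated mass.
    """
    q = libs.n2 / (libs.n1 + libs.n2)
    mean = _conditional_mean(x, libs)
    sd = math.sqrt((x + 1) * libs.n2 * (libs.n1 + libs.n2)) / libs.n1
    hi = int(max(y0, mean + 10 * sd + 20))
    acc = _log_sum_range(y0, hi, x, libs)
    while True:
        ratio = q * (x + hi + 2) / (hi + 2)
        if ratio < 1:
            # log of geometric bound on the mass beyond hi
            log_rem = float(log_conditional_pmf(hi + 1, x, libs)) - math.log1p(-ratio)
            if log_rem < acc + math.log(_TRUNCATION_EPS):
                return acc
        new_hi = hi + max(1000, hi // 2)
        acc = float(logsumexp([acc, _log_sum_range(hi + 1, new_hi, x, libs)]))
        hi = new_hi


def lower_tail(y: int, x: int, libs: LibraryPair) -> float:
    """Inclusive lower tail P(Y <= y | x).

    Summed directly from 0 when y sits below the conditional mean;
    otherwise computed as the complement of the (smaller) upper tail.
    """
    if y < 0:
        return 0.0
    if y <= _conditional_mean(x, libs):
        return min(1.0, math.exp(_log_sum_range(0, y, x, libs)))
    return max(0.0, 1.0 - math.exp(_log_upper_open(y + 1, x, libs)))


def upper_tail(y: int, x: int, libs: LibraryPair) -> float:
    """Inclusive upper tail P(Y >= y | x)."""
    if y <= 0:
        return 1.0
    if y > _conditional_mean(x, libs):
        return min(1.0, math.exp(_log_upper_open(y, x, libs)))
    return max(0.0, 1.0 - math.exp(_log_sum_range(0, y - 1, x, libs)))


def two_sided_p(counts: CountPair, libs: LibraryPair) -> ACResult:
    """Two-sided exact p-value for one tag's count pair.

    The larger count conditions; the smaller count is tested.  The
    p-value is twice the smaller of its inclusive tails, capped at 1.
    A tie in counts is conditioned on the side with the larger library
    total, keeping the result symmetric under a full library swap.
    """
    if counts.x > counts.y or (counts.x == counts.y and libs.n1 >= libs.n2):
        x_cond, y_test = counts.x, counts.y
        pair = libs
    else:
        x_cond, y_test = counts.y, counts.x
        pair = LibraryPair(libs.name_b, libs.name_a, libs.n2, libs.n1)
    lo = lower_tail(y_test, x_cond, pair)
    up = upper_tail(y_test, x_cond, pair)
    p = min(1.0, 2.0 * min(lo, up))
    return ACResult(p_value=p, lower_tail_mass=lo, upper_tail_mass=up)


def _largest_leq(predicate, lo: int, hi: int) -> int:
    """Largest y in [lo, hi] with predicate(y) True (monotone True->False)."""
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if predicate(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def confidence_interval(
    x: int, libs: LibraryPair, two_epsilon: float
) -> TailInterval:
    """The [y_min, y_max] interval at confidence 1 - two_epsilon given x.

    ``y_min`` is the largest y whose inclusive lower tail is <= eps
    (None when the lower tail already exceeds eps at y = 0); ``y_max``
    is the smallest y whose inclusive upper tail is <= eps.
    """
    if not 0 < two_epsilon < 1:
        raise ValueError(f"two_epsilon must lie in (0, 1), got {two_epsilon}")
    eps = two_epsilon / 2.0
    mean = _conditional_mean(x, libs)
    sd = math.sqrt((x + 1) * libs.n2 * (libs.n1 + libs.n2)) / libs.n1

    y_min: int | None
    if lower_tail(0, x, libs) > eps:
        y_min = None
    else:
        hi = int(mean + 10 * sd + 20)
        y_min = _largest_leq(lambda y: lower_tail(y, x, libs) <= eps, 0, hi)

    # upper_tail is non-increasing in y; find the smallest y with tail <= eps
    hi = int(mean + 10 * sd + 20)
    while upper_tail(hi, x, libs) > eps:
        hi *= 2
    lo = 0
    while lo < hi:
        mid = (lo + hi) // 2
        if upper_tail(mid, x, libs) <= eps:
            hi = mid
        else:
            lo = mid + 1
    y_max = hi

    return TailInterval(y_min=y_min, y_max=y_max, two_epsilon=two_epsilon)
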