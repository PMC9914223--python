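"""Gaver-Stehfest numerical inversion of Laplace transforms.

The Gaver-Stehfest algorithm approximates the original ``f(t)`` of a Laplace
transform ``F(s)`` using only evaluations of ``F`` at the real points
``s_j = j ln2 / t``::

    f(t) ~= (ln 2 / t) * sum_{j=1}^{N} V_j F(j ln2 / t)

with signed rational weights ``V_j`` that depend only on the (even) order
``N``.  The method is well suited to smooth, non-oscillatory originals such
as diffusion transients; it fails badly for oscillatory originals (see
:func:`invert` notes).

The weights are computed in exact integer/rational arithmetic
(:class:`fractions.Fraction`) and rounded to float once.  Naive floating
evaluation of the alternating factorial sums suffers catastrophic
cancellation — the weights for N=10 reach ~4e5 in magnitude while e.g. the
third weight is exactly 1279.

Accuracy notes (measured against closed-form transform pairs, exact
weights): at N=10 the scheme reproduces ``1/s -> 1`` to machine precision
(it satisfies ``sum V_j / j = 1`` exactly), but ``1/s**2 -> t`` only to
3.5e-5 relative — an intrinsic truncation error of the Gaver sequence, not
a rounding artifact — and ``1/(s+a) -> exp(-a t)`` degrades roughly
geometrically with ``a*t`` (~2e-6 at a*t <= 0.25, ~2.5e-4 at a*t = 1,
~1e-2 at a*t = 5).  Orders above 20 are rejected: the weights exceed 1e12
and double-precision evaluation of the weighted sum loses all accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Callable, List

import numpy as np

__all__ = ["StehfestScheme", "stehfest_weights", "stehfest_weights_exact", "invert"]

#: Largest supported inversion order (weights grow ~1.6e12 at N=20).
MAX_ORDER = 20

#: Order used throughout the package by default.
DEFAULT_ORDER = 10


def _validate_order(order: int) -> None:
    if not isinstance(order, (int, np.integer)):
        raise TypeError(f"order must be an integer, got {order!r}")
    if order <= 0 or order % 2 != 0:
        raise ValueError(f"order must be a positive even integer, got {order}")
    if order > MAX_ORDER:
        raise ValueError(
            f"order {order} exceeds the supported maximum {MAX_ORDER}; beyond this "
            "the weighted sum is meaningless in double precision"
        )


@lru_cache(maxsize=None)
def stehfest_weights_exact(order: int) -> tuple:
    """Exact rational Stehfest weights ``V_1..V_N`` for an even order.

    Returns a tuple of :class:`fractions.Fraction`.  The weights satisfy
    ``sum_j V_j == 0`` and ``sum_j V_j / j == 1`` exactly.
    """
    _validate_order(order)
    half = order // 2
    fact = math.factorial
    weights: List[Fraction] = []
    for j in range(1, order + 1):
        acc = Fraction(0)
        for k in range((j + 1) // 2, min(j, half) + 1):
            acc += Fraction(
                k**half * fact(2 * k),
                fact(half - k) * fact(k) * fact(k - 1) * fact(j - k) * fact(2 * k - j),
            )
        weights.append((-1) ** (half + j) * acc)
    return tuple(weights)


@dataclass(frozen=True)
class StehfestScheme:
    """An inversion order together with its weight vector.

    Parameters
    ----------
    order:
        Even positive integer N, at most 20.
    weights:
        The N signed weights ``V_1..V_N`` as floats, rounded once from the
        exact rational values.
    """

    order: int
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _validate_order(self.order)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.order,):
            raise ValueError(
                f"weights must have shape ({self.order},), got {w.shape}"
            )
        object.__setattr__(self, "weights", w)

    @property
    def sample_multipliers(self) -> np.ndarray:
        """The integers ``j = 1..N``; transform is sampled at ``j ln2/t``."""
        return np.arange(1, self.order + 1)


def stehfest_weights(order: int = DEFAULT_ORDER) -> StehfestScheme:
    """Build the Stehfest scheme of the given even order.

    The weights are computed in exact rational arithmetic and converted to
    float once (see module notes on cancellation).

    >>> stehfest_weights(2).weights
    array([ 2., -2.])
    """
    exact = stehfest_weights_exact(order)
    return StehfestScheme(order=int(order), weights=np.array([float(v) for v in exact]))


def invert(
    transform: Callable[[float], float],
    t: float,
    scheme: StehfestScheme | None = None,
) -> float:
    """Numerically invert a Laplace transform at time ``t > 0``.

    Parameters
    ----------
    transform:
        Callable returning ``F(s)`` for positive real ``s``.  Only real
        ``s`` values are ever passed.
    t:
        Time at which the original is wanted; must be strictly positive
        (the Stehfest sum is singular at ``t = 0``).
    scheme:
        Inversion scheme; defaults to order 10.

    Returns
    -------
    float
        ``(ln2/t) * sum_j V_j F(j ln2 / t)``.

    Raises
    ------
    ValueError
        If ``t <= 0``, or if the transform returns a non-finite value at
        one of the sample points (the offending ``s_j`` is named).

    Notes
    -----
    Oscillatory originals (e.g. ``s/(s**2+1) -> cos t``) are *not*
    accurately inverted by this method at any supported order; relative
    errors of order one must be expected.  Use it only for smooth
    monotone-ish transients.
    """
    if scheme is None:
        scheme = stehfest_weights(DEFAULT_ORDER)
    t = float(t)
    if not t > 0:
        raise ValueError(f"t must be strictly positive, got {t}")
    ln2_t = math.log(2.0) / t
    total = 0.0
    for j, v in zip(range(1, scheme.order + 1), scheme.weights):
        s_j = j * ln2_t
        value = transform(s_j)
        if not np.all(np.isfinite(value)):
            raise ValueError(
                f"transform returned a non-finite value at s_{j} = {s_j!r}"
            )
        total += v * value
    return ln2_t * total
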