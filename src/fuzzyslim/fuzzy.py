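"""Piecewise-linear convex fuzzy numbers and the operations the toolkit needs.

Expert judgments are elicited as linguistic terms and represented as
triangular ``(a1, a2, a3)`` or trapezoidal ``(a1, a2, a3, a4)`` fuzzy numbers:
membership is 0 outside the support ``[a1, a_last]``, 1 on the kernel, and
linear on the legs.  This module provides construction and validation, the
pointwise arithmetic used when aggregating opinions (scalar scaling, addition,
reciprocal), the pairwise similarity measure used by the similarity
aggregation method, and Chen–Hwang max–min defuzzification for numbers whose
support lies in the unit interval.

Only these convex piecewise-linear shapes are supported; general membership
functions and alternative t-norms are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "FuzzyNumber",
    "DefuzzScores",
    "make_fuzzy",
    "membership",
    "scale",
    "add",
    "reciprocal",
    "promote",
    "similarity",
    "defuzzify",
]


@dataclass(frozen=True)
class FuzzyNumber:
    """A triangular (3-point) or trapezoidal (4-point) fuzzy number.

    ``points`` are the non-decreasing breakpoints of the membership function.
    A crisp value ``v`` is the degenerate triangle ``(v, v, v)``.
    """

    points: tuple[float, ...]

    def __post_init__(self) -> None:
        pts = tuple(float(p) for p in self.points)
        if len(pts) not in (3, 4):
            raise ValueError(
                f"a fuzzy number needs 3 or 4 breakpoints, got {len(pts)}"
            )
        if not all(math.isfinite(p) for p in pts):
            raise ValueError(f"non-finite breakpoint in {pts}")
        if any(a > b for a, b in zip(pts, pts[1:])):
            raise ValueError(f"breakpoints must be non-decreasing, got {pts}")
        object.__setattr__(self, "points", pts)

    # -- shape ------------------------------------------------------------
    @property
    def is_triangular(self) -> bool:
        return len(self.points) == 3

    @property
    def is_trapezoidal(self) -> bool:
        return len(self.points) == 4

    @property
    def support(self) -> tuple[float, float]:
        return self.points[0], self.points[-1]

    @property
    def kernel(self) -> tuple[float, float]:
        """Interval where membership equals 1."""
        if self.is_triangular:
            return self.points[1], self.points[1]
        return self.points[1], self.points[2]

    # -- convenience arithmetic -------------------------------------------
    def __add__(self, other: "FuzzyNumber") -> "FuzzyNumber":
        return add(self, other)

    def __mul__(self, c: float) -> "FuzzyNumber":
        return scale(self, c)

    __rmul__ = __mul__

    def __call__(self, x: float) -> float:
        return membership(self, x)


@dataclass(frozen=True)
class DefuzzScores:
    """Chen–Hwang right (mu_R), left (mu_L) and total (mu_T) scores.

    Invariant: ``total == (right + 1 - left) / 2`` exactly.
    """

    right: float
    left: float
    total: float

    def __post_init__(self) -> None:
        if abs(self.total - (self.right + 1.0 - self.left) / 2.0) > 1e-12:
            raise ValueError("total must equal (right + 1 - left) / 2")


def make_fuzzy(points: Sequence[float]) -> FuzzyNumber:
    """Validate ``points`` (3 or 4 non-decreasing reals) into a FuzzyNumber.

    Unsorted input is rejected, never silently sorted.
    """
    return FuzzyNumber(tuple(points))


def membership(f: FuzzyNumber, x: float) -> float:
    """Piecewise-linear membership degree of ``x`` in ``f``, in [0, 1]."""
    lo, hi = f.support
    if x < lo or x > hi:
        return 0.0
    k_lo, k_hi = f.kernel
    if k_lo <= x <= k_hi:
        return 1.0
    if x < k_lo:  # rising leg; x < k_lo implies lo < k_lo so no zero division
        return (x - lo) / (k_lo - lo)
    return (hi - x) / (hi - k_hi)


def scale(f: FuzzyNumber, c: float) -> FuzzyNumber:
    """Scale by a nonnegative scalar, pointwise."""
    if c < 0:
        raise ValueError(f"scalar must be nonnegative, got {c}")
    return FuzzyNumber(tuple(c * p for p in f.points))


def add(f: FuzzyNumber, g: FuzzyNumber) -> FuzzyNumber:
    """Pointwise fuzzy addition; both operands must share the same arity."""
    if len(f.points) != len(g.points):
        raise ValueError(
            "cannot add fuzzy numbers of different arity "
            f"({len(f.points)} vs {len(g.points)}); promote() first"
        )
    return FuzzyNumber(tuple(a + b for a, b in zip(f.points, g.points)))


def reciprocal(f: FuzzyNumber) -> FuzzyNumber:
    """Fuzzy reciprocal: reversed pointwise inverses (1/a_last, ..., 1/a1).

    Defined only for positive support (exact on the 0- and 1-cuts).
    """
    if f.points[0] <= 0:
        raise ValueError(f"reciprocal needs strictly positive support, got {f.points}")
    return FuzzyNumber(tuple(1.0 / p for p in reversed(f.points)))


def promote(f: FuzzyNumber) -> FuzzyNumber:
    """Promote a triangular (a, b, c) to the trapezoid (a, b, b, c)."""
    if f.is_trapezoidal:
        return f
    a, b, c = f.points
    return FuzzyNumber((a, b, b, c))


def similarity(f: FuzzyNumber, g: FuzzyNumber) -> float:
    """Degree of agreement between two fuzzy opinions.

    ``S = 1 - (1/J) * sum_i |a_i - b_i|`` with J the common arity.  Mixed
    triangular/trapezoidal pairs are compared after promoting the triangle to
    a trapezoid (J = 4).  The value lies in [0, 1] when both opinions live in
    a universe of unit width, and equals 1 iff the opinions coincide.
    """
    if len(f.points) != len(g.points):
        f, g = promote(f), promote(g)
    j = len(f.points)
    return 1.0 - sum(abs(a - b) for a, b in zip(f.points, g.points)) / j


_UNIT_EPS = 1e-9


def defuzzify(f: FuzzyNumber) -> DefuzzScores:
    """Chen–Hwang max–min crisp score of a fuzzy number on [0, 1].

    The right score is ``sup_x min(mu_f(x), x)`` (intersection with the
    maximizing reference set ``mu_max(x) = x``), the left score is
    ``sup_x min(mu_f(x), 1 - x)``, and the total score is
    ``(right + 1 - left) / 2``.

    Closed forms: for support ``[a, d]`` with kernel ``[b, c]`` the reference
    line ``y = x`` always meets the falling leg, giving
    ``right = d / (1 + d - c)``; symmetrically ``left = (1 - a) / (1 + b - a)``.
    Degenerate (vertical) legs reduce continuously, e.g. ``right = d`` when
    ``c = d``.
    """
    lo, hi = f.support
    if lo < -_UNIT_EPS or hi > 1.0 + _UNIT_EPS:
        raise ValueError(
            f"defuzzification is defined on the unit interval; support {f.support} "
            "lies outside [0, 1] — rescale the linguistic scale first"
        )
    b, c = f.kernel
    a, d = lo, hi
    right = d / (1.0 + d - c)
    left = (1.0 - a) / (1.0 + b - a)
    total = (right + 1.0 - left) / 2.0
    return DefuzzScores(right=right, left=left, total=total)
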