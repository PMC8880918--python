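"""Fuzzy AHP by Chang's extent analysis for within-category factor weights.

Each performance-shaping-factor category holds a handful of concrete factors
(subPSFs).  Experts compare them pairwise using a five-term linguistic scale
of triangular fuzzy numbers (Equal (1,1,1) up to Very much more (2.5,3,3.5));
the reciprocal cell of a judgment holds the reversed pointwise inverses.

From a reciprocal fuzzy comparison matrix the method computes:

* fuzzy synthetic extents  S_i = (row-i fuzzy sum) (*) (grand fuzzy sum)^-1;
* degrees of possibility   V(M1 >= M2) — 1 when m1 >= m2, 0 when the
  supports are disjoint (l2 >= u1), otherwise the height of the
  intersection of M1's falling leg with M2's rising leg,
  (l2 - u1) / ((m1 - u1) - (m2 - l2));
* the unnormalized weight of criterion i, min over k != i of V(S_i >= S_k),
  normalized to sum to 1.

Saaty consistency ratios and multi-level hierarchies are out of scope
(category-level weights come from the consensus module instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fuzzy import FuzzyNumber, add, make_fuzzy, reciprocal

__all__ = [
    "DEFAULT_AHP_SCALE",
    "AHP_TERM_ORDER",
    "FuzzyPairwiseMatrix",
    "build_matrix",
    "aggregate_matrices",
    "synthetic_extents",
    "possibility",
    "weight_vector",
    "ahp_weights",
]

#: Linguistic comparison scale: term -> triangular fuzzy importance ratio.
DEFAULT_AHP_SCALE: Mapping[str, FuzzyNumber] = {
    "Equal importance": make_fuzzy((1.0, 1.0, 1.0)),
    "A little more importance": make_fuzzy((1.0, 1.5, 2.0)),
    "Relatively more importance": make_fuzzy((1.5, 2.0, 2.5)),
    "Much more importance": make_fuzzy((2.0, 2.5, 3.0)),
    "Very much more importance": make_fuzzy((2.5, 3.0, 3.5)),
}

#: Scale terms from indifference to strongest preference (the "ladder" used
#: by the synthetic generator when snapping ratios and perturbing judgments).
AHP_TERM_ORDER: tuple[str, ...] = tuple(DEFAULT_AHP_SCALE)

_RECIP_TOL = 1e-9


@dataclass(frozen=True)
class FuzzyPairwiseMatrix:
    """Reciprocal n x n matrix of triangular fuzzy judgments for one category."""

    labels: tuple[str, ...]
    cells: tuple[tuple[FuzzyNumber, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise ValueError("a pairwise matrix needs at least 2 criteria")
        if len(set(self.labels)) != n:
            raise ValueError(f"duplicate criterion labels in {self.labels}")
        if len(self.cells) != n or any(len(row) != n for row in self.cells):
            raise ValueError("cells must form an n x n grid matching labels")
        for i in range(n):
            if self.cells[i][i].points != (1.0, 1.0, 1.0):
                raise ValueError(
                    f"diagonal cell ({i},{i}) must be (1,1,1), "
                    f"got {self.cells[i][i].points}"
                )
            for j in range(i + 1, n):
                expect = reciprocal(self.cells[i][j]).points
                got = self.cells[j][i].points
                if any(abs(a - b) > _RECIP_TOL for a, b in zip(expect, got)):
                    raise ValueError(
                        f"cell ({j},{i}) {got} is not the reciprocal of "
                        f"cell ({i},{j}) {self.cells[i][j].points}"
                    )

    @property
    def n(self) -> int:
        return len(self.labels)

    def cell(self, a: str, b: str) -> FuzzyNumber:
        return self.cells[self.labels.index(a)][self.labels.index(b)]


def build_matrix(
    labels: Sequence[str],
    judgments: Sequence[tuple],
    scale: Mapping[str, FuzzyNumber] = DEFAULT_AHP_SCALE,
) -> FuzzyPairwiseMatrix:
    """Assemble a reciprocal matrix from one judgment per unordered pair.

    Each judgment is ``(a, b, term)`` or ``(a, b, term, direction)`` where
    the term states how much more important ``a`` is than ``b``; direction
    ``"b_over_a"`` flips it (i.e. the term is read as b over a, so cell
    (a, b) receives the reciprocal).  Missing or duplicated pairs and
    unknown terms or labels are rejected.
    """
    labels = tuple(labels)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    if len(idx) != n:
        raise ValueError(f"duplicate criterion labels in {labels}")
    one = make_fuzzy((1.0, 1.0, 1.0))
    cells: list[list[FuzzyNumber | None]] = [
        [one if i == j else None for j in range(n)] for i in range(n)
    ]
    seen: set[frozenset] = set()
    for judgment in judgments:
        if len(judgment) == 3:
            a, b, term = judgment
            direction = "a_over_b"
        elif len(judgment) == 4:
            a, b, term, direction = judgment
        else:
            raise ValueError(f"malformed judgment {judgment!r}")
        for lab in (a, b):
            if lab not in idx:
                raise ValueError(f"unknown criterion {lab!r} in judgment {judgment!r}")
        if a == b:
            raise ValueError(f"self-comparison {a!r} in judgment {judgment!r}")
        pair = frozenset((a, b))
        if pair in seen:
            raise ValueError(f"pair ({a}, {b}) judged more than once")
        seen.add(pair)
        if term not in scale:
            raise ValueError(
                f"unknown linguistic term {term!r} (known: {list(scale)})"
            )
        if direction not in ("a_over_b", "b_over_a"):
            raise ValueError(f"unknown direction {direction!r}")
        m = scale[term]
        if direction == "b_over_a":
            a, b = b, a
        i, j = idx[a], idx[b]
        cells[i][j] = m
        cells[j][i] = reciprocal(m)
    for i in range(n):
        for j in range(i + 1, n):
            if cells[i][j] is None:
                raise ValueError(
                    f"missing judgment for pair ({labels[i]}, {labels[j]})"
                )
    return FuzzyPairwiseMatrix(labels, tuple(tuple(row) for row in cells))


def aggregate_matrices(
    matrices: Sequence[FuzzyPairwiseMatrix],
    expert_weights: Sequence[float] | None = None,
) -> FuzzyPairwiseMatrix:
    """Combine per-expert matrices into one panel matrix.

    Cells are weighted arithmetic means of the experts' fuzzy judgments
    (uniform weights by default).  Because the mean of reciprocals is not the
    reciprocal of the mean, reciprocity is then re-imposed: each upper cell
    is replaced by the per-point geometric mean of itself and the reciprocal
    of its transpose cell, and the lower cell by that cell's reciprocal.
    A single matrix aggregates to itself.
    """
    if not matrices:
        raise ValueError("no matrices to aggregate")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError(
                f"label mismatch between matrices: {m.labels} vs {labels}"
            )
    k = len(matrices)
    if expert_weights is None:
        w = np.full(k, 1.0 / k)
    else:
        w = np.asarray(expert_weights, dtype=float)
        if w.size != k:
            raise ValueError(f"{k} matrices but {w.size} expert weights")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"expert weights must sum to 1, got {w.sum()}")
    n = len(labels)

    def mean_cell(i: int, j: int) -> tuple[float, ...]:
        pts = np.array([m.cells[i][j].points for m in matrices])
        return tuple(w @ pts)

    one = make_fuzzy((1.0, 1.0, 1.0))
    cells: list[list[FuzzyNumber]] = [[one] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            upper = mean_cell(i, j)
            mirror = reciprocal(make_fuzzy(mean_cell(j, i))).points
            repaired = make_fuzzy(
                tuple(float(np.sqrt(p * q)) for p, q in zip(upper, mirror))
            )
            cells[i][j] = repaired
            cells[j][i] = reciprocal(repaired)
    return FuzzyPairwiseMatrix(labels, tuple(tuple(row) for row in cells))


def synthetic_extents(matrix: FuzzyPairwiseMatrix) -> list[FuzzyNumber]:
    """Fuzzy synthetic extent S_i for each criterion.

    S_i is the fuzzy product of row i's sum with the inverse of the grand sum
    of all cells; with triangular cells (l, m, u) the inverse of the grand
    sum (L, M, U) is (1/U, 1/M, 1/L), so S_i = (l_i/U, m_i/M, u_i/L).
    """
    rows = []
    for row in matrix.cells:
        acc = row[0]
        for cell in row[1:]:
            acc = add(acc, cell)
        rows.append(acc)
    grand = rows[0]
    for r in rows[1:]:
        grand = add(grand, r)
    gl, gm, gu = grand.points
    return [
        make_fuzzy((l / gu, m / gm, u / gl)) for (l, m, u) in (r.points for r in rows)
    ]


def possibility(m1: FuzzyNumber, m2: FuzzyNumber) -> float:
    """Degree of possibility V(M1 >= M2) for triangular fuzzy numbers.

    1 when the first mode dominates (m1 >= m2); 0 when the supports are
    disjoint (l2 >= u1); otherwise the height at which M1's falling leg
    crosses M2's rising leg, (l2 - u1) / ((m1 - u1) - (m2 - l2)), which is
    the height of the membership intersection.
    """
    if not (m1.is_triangular and m2.is_triangular):
        raise ValueError("possibility degrees are defined for triangular numbers")
    l1, mid1, u1 = m1.points
    l2, mid2, u2 = m2.points
    if mid1 >= mid2:
        return 1.0
    if l2 >= u1:
        return 0.0
    denom = (mid1 - u1) - (mid2 - l2)
    if denom == 0.0:
        # both legs vertical; unreachable for valid triangulars once the two
        # guards above have fired, kept as the continuity limit
        return 1.0 if mid1 == mid2 else 0.0
    return (l2 - u1) / denom


def weight_vector(extents: Sequence[FuzzyNumber]) -> np.ndarray:
    """Chang weights from synthetic extents.

    W'_i = min over k != i of V(S_i >= S_k), normalized to sum to 1.  At
    least one W'_i is always 1 (the extent with the greatest mode dominates
    every pairwise comparison), so normalization is well defined for any
    valid extent set; an all-zero vector is still reported as an error
    rather than divided through.
    """
    n = len(extents)
    if n < 2:
        raise ValueError("need at least 2 extents")
    w = np.array(
        [
            min(possibility(extents[i], extents[k]) for k in range(n) if k != i)
            for i in range(n)
        ]
    )
    total = w.sum()
    if total <= 0:
        raise ValueError("no criterion dominates at any degree; cannot normalize")
    return w / total


def ahp_weights(
    matrices: Sequence[FuzzyPairwiseMatrix],
    expert_weights: Sequence[float] | None = None,
    mode: str = "pre-aggregate",
) -> dict[str, float]:
    """Panel comparison matrices -> normalized criterion weights.

    ``mode="pre-aggregate"`` (default) merges the panel's matrices first and
    derives one weight vector; ``"post-aggregate"`` derives a weight vector
    per expert and averages those with the expert weights.
    """
    if mode == "pre-aggregate":
        merged = aggregate_matrices(matrices, expert_weights)
        w = weight_vector(synthetic_extents(merged))
        labels = merged.labels
    elif mode == "post-aggregate":
        labels = matrices[0].labels
        per_expert = np.array(
            [weight_vector(synthetic_extents(m)) for m in matrices]
        )
        ew = (
            np.full(len(matrices), 1.0 / len(matrices))
            if expert_weights is None
            else np.asarray(expert_weights, dtype=float)
        )
        w = ew @ per_expert
        w = w / w.sum()
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return dict(zip(labels, (float(x) for x in w)))
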