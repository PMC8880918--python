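"""Seeded generators of synthetic elicitation data with known ground truth.

The raw inputs behind the published study — the ten-expert panel, its
linguistic importance judgments, and its pairwise comparison matrices — were
never published, so every pipeline stage is exercised here on generated data
whose ground truth is known by construction:

* a panel of experts with credentials sampled uniformly over the weighting
  scheme's levels (default size 10, the study's panel size);
* per-item opinions: each expert states the scale term nearest the item's
  true importance, drifting one term up or down with probability
  ``opinion_noise``;
* per-expert comparison matrices: each true ratio w_i/w_j is snapped to the
  nearest term of the five-step AHP ladder (or its reciprocal) and likewise
  perturbed one step with probability ``opinion_noise``;
* per-subtask category ratings drawn from a per-category normal profile and
  clipped to [1, 9]; the default profile matches the case study's column
  means and typical spread.

All randomness flows from the single ``seed``: each generator draws from its
own stream, derived as ``SeedSequence([seed, stream_index])``, so generators
are individually and jointly reproducible.

Ground-truth weight vectors sampled here keep a minimum ratio of 1.25
between adjacent sorted weights — half a step on the linguistic ladder,
whose modal ratios advance by 0.5 — because closer importances cannot be
expressed in the elicitation vocabulary at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ahp import AHP_TERM_ORDER, FuzzyPairwiseMatrix, build_matrix
from .consensus import (
    DEFAULT_OPINION_SCALE,
    ExpertProfile,
    OpinionSet,
    WeightingScheme,
    DEFAULT_SCHEME,
    expert_weights,
)
from .fuzzy import FuzzyNumber
from .slim import CATEGORIES, RatingSheet, SubtaskRating
from .taxonomy import TaskAnalysis

__all__ = [
    "SyntheticSpec",
    "gen_panel",
    "gen_opinions",
    "gen_matrices",
    "gen_ratings",
    "sample_true_weights",
]

_STREAMS = {"panel": 0, "opinions": 1, "matrices": 2, "ratings": 3, "weights": 4}

#: Modal importance ratios of the AHP ladder, indifference upward.
_LADDER_MODES = np.array([1.0, 1.5, 2.0, 2.5, 3.0])


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic elicitation exercise.

    ``true_weights`` (summing to 1) drive both opinion and matrix
    generation; ``None`` means equal importance.  ``rating_profile`` maps
    each category to a (mean, sd) pair on the 1-9 rating scale.
    """

    seed: int
    n_experts: int = 10
    n_criteria: int = 3
    true_weights: tuple[float, ...] | None = None
    opinion_noise: float = 0.1
    rating_profile: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "personal": (6.2, 0.2),
            "job": (4.1, 0.4),
            "organization": (4.2, 0.6),
        }
    )

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ValueError("need at least 2 experts")
        if self.n_criteria < 2:
            raise ValueError("need at least 2 criteria")
        if not 0.0 <= self.opinion_noise <= 1.0:
            raise ValueError("opinion_noise must lie in [0, 1]")
        if self.true_weights is not None:
            w = np.asarray(self.true_weights, dtype=float)
            if w.size != self.n_criteria:
                raise ValueError("true_weights length must equal n_criteria")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("true_weights must be nonnegative and sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[stream]])
        )

    @property
    def weights(self) -> np.ndarray:
        if self.true_weights is None:
            return np.full(self.n_criteria, 1.0 / self.n_criteria)
        return np.asarray(self.true_weights, dtype=float)


def sample_true_weights(
    rng: np.random.Generator,
    n_criteria: int,
    min_adjacent_ratio: float = 1.25,
    max_extreme_ratio: float = 3.5,
) -> tuple[float, ...]:
    """Sample a normalized weight vector expressible on the judgment ladder.

    Adjacent sorted weights differ by at least ``min_adjacent_ratio`` (the
    boundary below which a ratio snaps to "Equal importance", making the
    pair indistinguishable) and the extreme ratio stays below
    ``max_extreme_ratio`` (the ladder saturates at "Very much more", support
    up to 3.5, so larger true ratios cannot be voiced).  The log-ratio gaps
    between adjacent weights are drawn uniformly within those bounds and the
    order is randomly permuted.
    """
    if n_criteria < 2:
        raise ValueError("need at least 2 criteria")
    k = n_criteria - 1
    base = k * np.log(min_adjacent_ratio)
    cap = np.log(max_extreme_ratio)
    if base > cap:
        raise ValueError(
            f"{n_criteria} criteria cannot all differ by {min_adjacent_ratio}x "
            f"within an extreme ratio of {max_extreme_ratio}"
        )
    span = rng.uniform(base, cap)
    gaps = np.log(min_adjacent_ratio) + rng.dirichlet(np.ones(k)) * (span - base)
    w = np.exp(np.concatenate([[0.0], np.cumsum(gaps)]))
    w /= w.sum()
    return tuple(float(x) for x in w[rng.permutation(n_criteria)])


def _expert_ids(n: int) -> list[str]:
    return [f"E{i + 1}" for i in range(n)]


def gen_panel(
    spec: SyntheticSpec, scheme: WeightingScheme = DEFAULT_SCHEME
) -> list[ExpertProfile]:
    """Generate a weighted expert panel with uniformly sampled credentials."""
    rng = spec.rng("panel")
    experience_levels = [2.0, 7.0, 15.0, 25.0]  # one representative per bin
    educations = list(scheme.education_levels)
    relevancies = list(scheme.relevancy_levels)
    profiles = [
        ExpertProfile(
            eid,
            float(rng.choice(experience_levels)),
            str(rng.choice(educations)),
            str(rng.choice(relevancies)),
        )
        for eid in _expert_ids(spec.n_experts)
    ]
    return expert_weights(profiles, scheme)


def gen_opinions(
    spec: SyntheticSpec,
    items: Sequence[str] | None = None,
    scale: Mapping[str, FuzzyNumber] = DEFAULT_OPINION_SCALE,
) -> list[OpinionSet]:
    """Generate each expert's linguistic opinion on each item.

    An item's true importance is its weight rescaled so the most important
    item sits at the top of the [0, 1] universe; each expert reports the
    scale term nearest that importance, drifting one term with probability
    ``opinion_noise``.
    """
    rng = spec.rng("opinions")
    w = spec.weights
    if items is None:
        items = (
            list(CATEGORIES)
            if spec.n_criteria == 3
            else [f"item{i + 1}" for i in range(spec.n_criteria)]
        )
    if len(items) != spec.n_criteria:
        raise ValueError("items length must equal n_criteria")
    terms = list(scale)
    # anchor terms at their modal (kernel-midpoint) importance
    anchors = np.array([sum(scale[t].kernel) / 2.0 for t in terms])
    importance = w / w.max()
    experts = _expert_ids(spec.n_experts)
    sets = []
    for item, x in zip(items, importance):
        base = int(np.argmin(np.abs(anchors - x)))
        opinions = {}
        for eid in experts:
            k = base
            if rng.random() < spec.opinion_noise:
                k = min(max(k + (1 if rng.random() < 0.5 else -1), 0), len(terms) - 1)
            opinions[eid] = scale[terms[k]]
        sets.append(OpinionSet(item, opinions))
    return sets


def _snap_ratio(ratio: float) -> int:
    """Signed ladder position of a true importance ratio.

    0 is indifference; +k means the row criterion is k steps more important,
    -k the reverse.  Ratios beyond the ladder saturate at the last term.
    """
    r = ratio if ratio >= 1.0 else 1.0 / ratio
    step = int(np.argmin(np.abs(_LADDER_MODES - min(r, _LADDER_MODES[-1]))))
    return step if ratio >= 1.0 else -step


def gen_matrices(
    spec: SyntheticSpec, labels: Sequence[str] | None = None
) -> list[FuzzyPairwiseMatrix]:
    """Generate one snapped-and-perturbed comparison matrix per expert."""
    rng = spec.rng("matrices")
    w = spec.weights
    if labels is None:
        labels = [f"C{i + 1}" for i in range(spec.n_criteria)]
    n = spec.n_criteria
    top = len(AHP_TERM_ORDER) - 1
    matrices = []
    for _ in range(spec.n_experts):
        judgments = []
        for i in range(n):
            for j in range(i + 1, n):
                s = _snap_ratio(w[i] / w[j])
                if rng.random() < spec.opinion_noise:
                    s = min(max(s + (1 if rng.random() < 0.5 else -1), -top), top)
                term = AHP_TERM_ORDER[abs(s)]
                direction = "a_over_b" if s >= 0 else "b_over_a"
                judgments.append((labels[i], labels[j], term, direction))
        matrices.append(build_matrix(labels, judgments))
    return matrices


def gen_ratings(spec: SyntheticSpec, tasks: TaskAnalysis) -> RatingSheet:
    """Generate category-level ratings for every subtask of ``tasks``."""
    rng = spec.rng("ratings")
    for cat in CATEGORIES:
        if cat not in spec.rating_profile:
            raise ValueError(f"rating_profile is missing category {cat!r}")
        mean, sd = spec.rating_profile[cat]
        if sd < 0:
            raise ValueError(f"negative rating spread for {cat!r}")
    entries = {}
    for sid in tasks.subtask_ids:
        ratings = {}
        for cat in CATEGORIES:
            mean, sd = spec.rating_profile[cat]
            r = mean if sd == 0 else float(rng.normal(mean, sd))
            ratings[cat] = float(np.clip(r, 1.0, 9.0))
        entries[sid] = SubtaskRating(sid, "category", ratings)
    return RatingSheet(entries)
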