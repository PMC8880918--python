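"""Success Likelihood Index Methodology (SLIM) engine.

The probability of a human (here: medication) error in a subtask is modelled
as a log-linear function of a Success Likelihood Index,

    SLI = sum_i R_i * W_i,        1 <= SLI <= 9,
    log10(HEP) = a * SLI + b,

where R_i are ratings of the performance shaping factors on a 1 (worst
situation) to 9 (best situation) scale, W_i their weights, and the constants
(a, b) are calibrated so that the worst achievable index maps to the highest
credible error probability and the best index to the lowest.  With the
default bounds HEP(SLI=1) = 1 and HEP(SLI=9) = 1e-4, the constants are
a = -0.5 and b = 0.5.

Category ratings can be supplied directly or computed from subPSF ratings as
the weight-weighted sum R = sum_i r_i * w_i over the category's factors.
Category weights default to the published emergency-department study values
(0.367, 0.311, 0.321) — note these printed coefficients sum to 0.999, so the
best achievable SLI is 8.991; full-precision weights recomputed from a panel
can be substituted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

__all__ = [
    "Calibration",
    "CategoryWeights",
    "SubtaskRating",
    "RatingSheet",
    "HEPResult",
    "PUBLISHED_CATEGORY_WEIGHTS",
    "DEFAULT_CALIBRATION",
    "CATEGORIES",
    "calibrate",
    "category_rating",
    "sli",
    "hep",
    "assess",
    "extremes",
]

if TYPE_CHECKING:  # pragma: no cover
    from .taxonomy import PSFTaxonomy, TaskAnalysis

#: Canonical category order: personal, job, organization.
CATEGORIES: tuple[str, str, str] = ("personal", "job", "organization")

RATING_MIN, RATING_MAX = 1.0, 9.0


@dataclass(frozen=True)
class Calibration:
    """Constants of the log-linear SLI -> HEP map and the bounds behind them.

    Invariants: ``hep(sli_min) == hep_max`` and ``hep(sli_max) == hep_min``
    exactly (base-10), hence ``a < 0`` — a better situation (higher SLI)
    yields a lower error probability.
    """

    a: float
    b: float
    hep_min: float
    hep_max: float
    sli_min: float
    sli_max: float

    def __post_init__(self) -> None:
        if not (0.0 < self.hep_min < self.hep_max <= 1.0):
            raise ValueError(
                f"need 0 < hep_min < hep_max <= 1, got ({self.hep_min}, {self.hep_max})"
            )
        if self.sli_min >= self.sli_max:
            raise ValueError("degenerate SLI range")
        for s, h in ((self.sli_min, self.hep_max), (self.sli_max, self.hep_min)):
            if abs(self.a * s + self.b - math.log10(h)) > 1e-12:
                raise ValueError("constants do not satisfy the calibration bounds")


def calibrate(
    hep_min: float = 1e-4,
    hep_max: float = 1.0,
    sli_min: float = 1.0,
    sli_max: float = 9.0,
) -> Calibration:
    """Solve the two-point system for (a, b) in log10 space.

    ``log10(hep_max) = a*sli_min + b`` and ``log10(hep_min) = a*sli_max + b``.
    """
    if not (0.0 < hep_min < hep_max <= 1.0):
        raise ValueError(f"need 0 < hep_min < hep_max <= 1, got ({hep_min}, {hep_max})")
    if sli_min >= sli_max:
        raise ValueError(f"degenerate SLI range [{sli_min}, {sli_max}]")
    a = (math.log10(hep_min) - math.log10(hep_max)) / (sli_max - sli_min)
    b = math.log10(hep_max) - a * sli_min
    return Calibration(a, b, hep_min, hep_max, sli_min, sli_max)


DEFAULT_CALIBRATION = calibrate()


@dataclass(frozen=True)
class CategoryWeights:
    """Weights of the personal, job and organization categories in the SLI."""

    personal: float
    job: float
    organization: float

    def __post_init__(self) -> None:
        vals = (self.personal, self.job, self.organization)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError(f"category weights must lie in [0, 1], got {vals}")
        if not 0.99 <= sum(vals) <= 1.01:
            raise ValueError(
                f"category weights must sum to ~1, got {sum(vals):.4f}"
            )

    def as_mapping(self) -> dict[str, float]:
        return {
            "personal": self.personal,
            "job": self.job,
            "organization": self.organization,
        }


#: Coefficients of the published emergency-department SLI equation
#: (printed to three decimals; they sum to 0.999).
PUBLISHED_CATEGORY_WEIGHTS = CategoryWeights(0.367, 0.311, 0.321)


@dataclass(frozen=True)
class SubtaskRating:
    """Ratings for one subtask, at category or subPSF level.

    ``level`` is ``"category"`` (keys are the three category names) or
    ``"subpsf"`` (keys are subPSF labels from the taxonomy).  All ratings lie
    in [1, 9]; 9 is the best situation.
    """

    subtask_id: str
    level: str
    ratings: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.level not in ("category", "subpsf"):
            raise ValueError(
                f"subtask {self.subtask_id}: level must be 'category' or "
                f"'subpsf', got {self.level!r}"
            )
        for name, r in self.ratings.items():
            if not RATING_MIN <= r <= RATING_MAX:
                raise ValueError(
                    f"subtask {self.subtask_id}: rating {r} for {name!r} "
                    f"outside [{RATING_MIN:g}, {RATING_MAX:g}]"
                )
        if self.level == "category":
            missing = [c for c in CATEGORIES if c not in self.ratings]
            if missing:
                raise ValueError(
                    f"subtask {self.subtask_id}: missing category ratings {missing}"
                )


@dataclass(frozen=True)
class RatingSheet:
    """Per-subtask ratings for a whole task analysis."""

    entries: Mapping[str, SubtaskRating]

    def __post_init__(self) -> None:
        for sid, entry in self.entries.items():
            if sid != entry.subtask_id:
                raise ValueError(f"key {sid!r} != entry id {entry.subtask_id!r}")


@dataclass(frozen=True)
class HEPResult:
    """Assessment outcome for one subtask (one row of the final report)."""

    subtask_id: str
    r_personal: float
    r_job: float
    r_organization: float
    sli: float
    hep: float


def category_rating(
    ratings: Mapping[str, float], weights: Mapping[str, float]
) -> float:
    """Rating of a category from its subPSF ratings: R = sum_i r_i * w_i."""
    total_w = sum(weights.values())
    if not 0.99 <= total_w <= 1.01:
        raise ValueError(f"subPSF weights must sum to ~1, got {total_w:.4f}")
    missing = [name for name in weights if name not in ratings]
    if missing:
        raise ValueError(f"missing ratings for weighted subPSFs: {missing}")
    return sum(ratings[name] * w for name, w in weights.items())


def sli(
    r_personal: float,
    r_job: float,
    r_organization: float,
    weights: CategoryWeights = PUBLISHED_CATEGORY_WEIGHTS,
) -> float:
    """Success Likelihood Index: the category-weighted sum of ratings."""
    for name, r in zip(CATEGORIES, (r_personal, r_job, r_organization)):
        if not RATING_MIN <= r <= RATING_MAX:
            raise ValueError(
                f"{name} rating {r} outside [{RATING_MIN:g}, {RATING_MAX:g}]"
            )
    return (
        weights.personal * r_personal
        + weights.job * r_job
        + weights.organization * r_organization
    )


def hep(sli_value: float, cal: Calibration = DEFAULT_CALIBRATION) -> float:
    """Human error probability 10**(a*SLI + b), reported within the bounds.

    An index outside the nominal calibration range is warned about (printed
    category weights summing to 0.999 cap the index at 8.991, which is still
    inside [1, 9]) and the probability is clamped to [hep_min, hep_max].
    """
    if sli_value < cal.sli_min or sli_value > cal.sli_max:
        warnings.warn(
            f"SLI {sli_value:.4g} outside nominal range "
            f"[{cal.sli_min:g}, {cal.sli_max:g}]; HEP clamped to bounds",
            stacklevel=2,
        )
    p = 10.0 ** (cal.a * sli_value + cal.b)
    return min(max(p, cal.hep_min), cal.hep_max)


def _category_ratings(
    entry: SubtaskRating, taxonomy: "PSFTaxonomy | None"
) -> tuple[float, float, float]:
    if entry.level == "category":
        return tuple(entry.ratings[c] for c in CATEGORIES)  # type: ignore[return-value]
    if taxonomy is None:
        raise ValueError(
            f"subtask {entry.subtask_id} is rated at subPSF level; "
            "a taxonomy with subPSF weights is required"
        )
    return tuple(  # type: ignore[return-value]
        category_rating(entry.ratings, taxonomy.weights(c)) for c in CATEGORIES
    )


def assess(
    tasks: "TaskAnalysis",
    sheet: RatingSheet,
    taxonomy: "PSFTaxonomy | None" = None,
    weights: CategoryWeights = PUBLISHED_CATEGORY_WEIGHTS,
    cal: Calibration = DEFAULT_CALIBRATION,
) -> list[HEPResult]:
    """Compute SLI and HEP for every subtask of a task analysis.

    Every subtask must be rated (at either level); results come back in task
    order.  An empty task analysis yields an empty list.
    """
    results: list[HEPResult] = []
    for sid in tasks.subtask_ids:
        entry = sheet.entries.get(sid)
        if entry is None:
            raise ValueError(f"subtask {sid} has no ratings")
        r_p, r_j, r_o = _category_ratings(entry, taxonomy)
        s = sli(r_p, r_j, r_o, weights)
        results.append(HEPResult(sid, r_p, r_j, r_o, s, hep(s, cal)))
    return results


def extremes(results: Sequence[HEPResult]) -> tuple[list[str], list[str]]:
    """Ids of the max-HEP and min-HEP subtasks (ties kept, id-sorted)."""
    if not results:
        return [], []
    hi = max(r.hep for r in results)
    lo = min(r.hep for r in results)
    worst = sorted(r.subtask_id for r in results if r.hep == hi)
    best = sorted(r.subtask_id for r in results if r.hep == lo)
    return worst, best
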