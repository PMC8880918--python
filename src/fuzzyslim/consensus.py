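"""Similarity aggregation method (SAM) for panel-based PSF weighting.

A panel of experts states, in linguistic terms, how important each
performance shaping factor (PSF) is for producing human error.  The fuzzy
multiple attributive group decision making (FMAGDM) pipeline implemented
here turns those opinions into one normalized weight per factor:

1. each expert's linguistic term maps to a fuzzy number on [0, 1];
2. pairwise inter-expert agreement S_uv = similarity of the two opinions;
3. average agreement AA(E_u) = mean of S_uv over v != u;
4. relative agreement RA(E_u) = AA(E_u) / sum_v AA(E_v);
5. consensus coefficient CC(E_u) = beta * W(E_u) + (1 - beta) * RA(E_u),
   where W(E_u) is the expert's importance weight and beta in [0, 1] blends
   credentials against agreement (beta = 0 treats all experts as equally
   important);
6. the aggregated opinion R_AG = sum_u CC(E_u) * R(E_u);
7. R_AG is defuzzified with the Chen-Hwang max-min total score;
8. total scores are normalized across factors into weights summing to 1.

The default blending coefficient is beta = 0.4.

The elicitation vocabulary used by the original panel was published only as
a figure, so :data:`DEFAULT_OPINION_SCALE` is this package's own 7-term
triangular scale on [0, 1]; any scale can be supplied instead (see
``taxonomy.load_scale``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fuzzy import FuzzyNumber, add, defuzzify, make_fuzzy, scale, similarity

__all__ = [
    "ExpertProfile",
    "OpinionSet",
    "ConsensusTrace",
    "WeightingScheme",
    "DEFAULT_SCHEME",
    "UNIFORM_SCHEME",
    "DEFAULT_OPINION_SCALE",
    "DEFAULT_BETA",
    "expert_weights",
    "agreement_matrix",
    "average_agreement",
    "relative_agreement",
    "consensus_coefficients",
    "aggregate",
    "sam_aggregate",
    "psf_weights",
]

DEFAULT_BETA = 0.4

#: Package-default 7-term elicitation scale on [0, 1].  Not taken from any
#: published membership functions; override via configuration when the panel
#: used a different vocabulary.
DEFAULT_OPINION_SCALE: Mapping[str, FuzzyNumber] = {
    "very low": make_fuzzy((0.0, 0.0, 0.1)),
    "low": make_fuzzy((0.0, 0.1, 0.3)),
    "medium low": make_fuzzy((0.1, 0.3, 0.5)),
    "medium": make_fuzzy((0.3, 0.5, 0.7)),
    "medium high": make_fuzzy((0.5, 0.7, 0.9)),
    "high": make_fuzzy((0.7, 0.9, 1.0)),
    "very high": make_fuzzy((0.9, 1.0, 1.0)),
}


@dataclass
class ExpertProfile:
    """Panel member with the attributes used for importance weighting.

    ``experience`` is in years; ``education`` and ``relevancy`` are ordinal
    labels defined by the weighting scheme.  ``weight`` is W(E_u), filled in
    by :func:`expert_weights`; panel weights sum to 1.
    """

    id: str
    experience: float
    education: str
    relevancy: str
    weight: float | None = None


@dataclass(frozen=True)
class OpinionSet:
    """One item (PSF or subPSF) with each expert's fuzzy opinion on it."""

    item: str
    opinions: Mapping[str, FuzzyNumber]

    def __post_init__(self) -> None:
        if len(self.opinions) < 2:
            raise ValueError(
                f"item {self.item!r}: a panel needs at least 2 opinions"
            )


@dataclass(frozen=True)
class ConsensusTrace:
    """Full audit trail of one SAM aggregation."""

    item: str
    experts: tuple[str, ...]
    agreement: np.ndarray            # m x m, S_uv, symmetric, unit diagonal
    average_agreement: np.ndarray    # AA(E_u)
    relative_agreement: np.ndarray   # RA(E_u), sums to 1
    consensus: np.ndarray            # CC(E_u), sums to 1
    beta: float
    aggregate: FuzzyNumber           # R_AG
    defuzzified: float               # Chen-Hwang total score of R_AG


# --------------------------------------------------------------------------
# Expert importance weights
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightingScheme:
    """Additive ordinal scoring of expert credentials.

    Experience in years is binned by ``experience_bins`` (score = 1 + number
    of thresholds reached); education and relevancy map through their level
    tables.  An expert's score is the sum of the three, and weights are the
    scores normalized across the panel.  ``uniform=True`` ignores credentials
    and returns 1/m everywhere (the natural companion to beta = 0).
    """

    experience_bins: tuple[float, ...] = (5.0, 10.0, 20.0)
    education_levels: Mapping[str, int] = field(
        default_factory=lambda: {"diploma": 1, "bachelor": 2, "master": 3, "phd": 4}
    )
    relevancy_levels: Mapping[str, int] = field(
        default_factory=lambda: {"low": 1, "medium": 2, "high": 3}
    )
    uniform: bool = False

    def score(self, p: ExpertProfile) -> float:
        if p.experience < 0:
            raise ValueError(f"expert {p.id}: negative experience")
        exp_score = 1 + sum(p.experience >= t for t in self.experience_bins)
        try:
            edu_score = self.education_levels[p.education.strip().lower()]
        except KeyError:
            raise ValueError(
                f"expert {p.id}: unknown education level {p.education!r} "
                f"(known: {sorted(self.education_levels)})"
            ) from None
        try:
            rel_score = self.relevancy_levels[p.relevancy.strip().lower()]
        except KeyError:
            raise ValueError(
                f"expert {p.id}: unknown relevancy level {p.relevancy!r} "
                f"(known: {sorted(self.relevancy_levels)})"
            ) from None
        return float(exp_score + edu_score + rel_score)


DEFAULT_SCHEME = WeightingScheme()
UNIFORM_SCHEME = WeightingScheme(uniform=True)


def expert_weights(
    profiles: Sequence[ExpertProfile],
    scheme: WeightingScheme | str = DEFAULT_SCHEME,
) -> list[ExpertProfile]:
    """Assign normalized importance weights W(E_u) to a panel.

    ``scheme`` may be a :class:`WeightingScheme` or the presets ``"default"``
    / ``"uniform"``.  Returns new profiles; weights sum to 1.
    """
    if not profiles:
        raise ValueError("empty panel")
    if isinstance(scheme, str):
        try:
            scheme = {"default": DEFAULT_SCHEME, "uniform": UNIFORM_SCHEME}[scheme]
        except KeyError:
            raise ValueError(f"unknown weighting scheme {scheme!r}") from None
    if scheme.uniform:
        scores = [1.0] * len(profiles)
    else:
        scores = [scheme.score(p) for p in profiles]
    total = sum(scores)
    return [
        ExpertProfile(p.id, p.experience, p.education, p.relevancy, s / total)
        for p, s in zip(profiles, scores)
    ]


# --------------------------------------------------------------------------
# SAM steps
# --------------------------------------------------------------------------

def agreement_matrix(opinions: Sequence[FuzzyNumber]) -> np.ndarray:
    """Pairwise degree-of-agreement matrix S_uv (symmetric, unit diagonal)."""
    m = len(opinions)
    s = np.eye(m)
    for u in range(m):
        for v in range(u + 1, m):
            s[u, v] = s[v, u] = similarity(opinions[u], opinions[v])
    return s


def average_agreement(agreement: np.ndarray) -> np.ndarray:
    """AA(E_u): mean agreement of expert u with the other m-1 experts."""
    agreement = np.asarray(agreement, dtype=float)
    m = agreement.shape[0]
    if m < 2:
        raise ValueError("panel too small: average agreement needs m >= 2 experts")
    return (agreement.sum(axis=1) - agreement.diagonal()) / (m - 1)


def relative_agreement(aa: np.ndarray) -> np.ndarray:
    """RA(E_u) = AA(E_u) / sum_v AA(E_v); sums to 1."""
    aa = np.asarray(aa, dtype=float)
    total = aa.sum()
    if total <= 0:
        raise ValueError("complete disagreement: average agreements sum to zero")
    return aa / total


def consensus_coefficients(
    ra: np.ndarray, weights: np.ndarray, beta: float = DEFAULT_BETA
) -> np.ndarray:
    """CC(E_u) = beta * W(E_u) + (1 - beta) * RA(E_u).

    With W and RA each summing to 1, CC sums to 1 for any beta in [0, 1];
    beta = 0 reduces to RA (all experts equally important), beta = 1 to W.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    ra = np.asarray(ra, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ra.shape != weights.shape:
        raise ValueError("RA and expert-weight vectors differ in length")
    return beta * weights + (1.0 - beta) * ra


def aggregate(
    opinions: Sequence[FuzzyNumber], cc: np.ndarray
) -> FuzzyNumber:
    """R_AG = sum_u CC(E_u) * R(E_u), the consensus fuzzy opinion."""
    cc = np.asarray(cc, dtype=float)
    if len(opinions) != cc.size:
        raise ValueError(
            f"{len(opinions)} opinions but {cc.size} consensus coefficients"
        )
    acc = scale(opinions[0], float(cc[0]))
    for f, c in zip(opinions[1:], cc[1:]):
        acc = add(acc, scale(f, float(c)))
    return acc


def sam_aggregate(
    opinion_set: OpinionSet,
    panel: Sequence[ExpertProfile],
    beta: float = DEFAULT_BETA,
) -> ConsensusTrace:
    """Run the full SAM chain for one item and return its audit trace."""
    ids = tuple(p.id for p in panel)
    missing = [e for e in ids if e not in opinion_set.opinions]
    if missing:
        raise ValueError(
            f"item {opinion_set.item!r}: missing opinions from experts {missing}"
        )
    extra = [e for e in opinion_set.opinions if e not in ids]
    if extra:
        raise ValueError(
            f"item {opinion_set.item!r}: opinions from unknown experts {extra}"
        )
    w = np.array([p.weight for p in panel], dtype=float)
    if any(p.weight is None for p in panel):
        raise ValueError("panel weights not assigned; run expert_weights() first")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"panel weights must sum to 1, got {w.sum()}")
    fuzzies = [opinion_set.opinions[e] for e in ids]
    s = agreement_matrix(fuzzies)
    aa = average_agreement(s)
    ra = relative_agreement(aa)
    cc = consensus_coefficients(ra, w, beta)
    r_ag = aggregate(fuzzies, cc)
    total = defuzzify(r_ag).total
    return ConsensusTrace(
        item=opinion_set.item,
        experts=ids,
        agreement=s,
        average_agreement=aa,
        relative_agreement=ra,
        consensus=cc,
        beta=beta,
        aggregate=r_ag,
        defuzzified=total,
    )


def psf_weights(
    panel: Sequence[ExpertProfile],
    opinion_sets: Sequence[OpinionSet],
    beta: float = DEFAULT_BETA,
) -> tuple[dict[str, float], dict[str, ConsensusTrace]]:
    """Panel judgments on a set of factors -> normalized factor weights.

    Every item is aggregated with the same panel, defuzzified, and the total
    scores are normalized to sum to 1 across items (full precision — no
    intermediate rounding).  Returns ``(weights, traces)`` keyed by item.
    """
    if not opinion_sets:
        raise ValueError("no items to weigh")
    traces = {s.item: sam_aggregate(s, panel, beta) for s in opinion_sets}
    totals = {item: t.defuzzified for item, t in traces.items()}
    norm = sum(totals.values())
    if norm <= 0:
        raise ValueError("all defuzzified scores are zero; cannot normalize")
    weights = {item: v / norm for item, v in totals.items()}
    return weights, traces
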