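# Methods

## Model

The package treats a medication-handling workflow as a hierarchical task
analysis (tasks → subtasks) and assigns each subtask a human error
probability (HEP) through the Success Likelihood Index Methodology:

* `SLI = Σ Rᵢ·Wᵢ` over performance shaping factors (PSFs), with ratings
  `Rᵢ ∈ [1, 9]` (9 = best situation) and weights `Wᵢ ≥ 0` summing to ≈ 1;
* `log₁₀(HEP) = a·SLI + b`, with `(a, b)` solved from two anchor points,
  `HEP(sli_min) = hep_max` and `HEP(sli_max) = hep_min`.

Assumptions inherited from SLIM: factors act additively on the log scale
(no interactions between PSFs), the anchor probabilities are known or
defensible, and ratings are comparable across subtasks.  The log base is
10: only base 10 makes the default anchors `(10⁻⁴, 1)` over `SLI ∈ [1, 9]`
yield `a = −0.5, b = 0.5` and reproduce the bundled case-study HEP column;
the natural-log reading of the same constants misses it by orders of
magnitude (asserted in the acceptance tests).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `hep_min`, `hep_max` | 10⁻⁴, 1 | error probabilities at the best/worst index; dimensionless probabilities |
| `sli_min`, `sli_max` | 1, 9 | nominal index range (the rating scale's ends) |
| β | 0.4 | blend of expert credential weight vs. inter-expert agreement in the consensus coefficient; β = 0 treats all experts as equally important |
| category weights | 0.367 / 0.311 / 0.321 | published emergency-department coefficients (personal/job/organization) |
| subPSF weights | bundled taxonomy | published fuzzy-AHP output per category |

The published category weights are printed to three decimals and sum to
0.999, so the best achievable SLI under them is 8.991 (HEP ≈ 1.01·10⁻⁴,
just above the lower anchor).  The calibration keeps the nominal [1, 9]
range; an index outside it is warned about and the probability clamped to
the anchors.  Two weight modes exist: *published* (the printed coefficients,
used verbatim for the bundled case study, since only they reproduce the
printed table) and *recompute* (full-precision consensus output, normalized
exactly, no intermediate rounding).

## Expert weighting

The elicitation protocol weighs experts by work experience, education and
relevancy but fixes no formula; the package's documented default is an
additive ordinal score: experience years binned at 5/10/20 (score 1–4),
education diploma/bachelor/master/phd (1–4), relevancy low/medium/high
(1–3); summed scores are normalized across the panel.  A `uniform` preset
ignores credentials (the natural companion of β = 0).  Both are
configuration, not doctrine — any `WeightingScheme` can be supplied.

## Fuzzy machinery and numerical choices

* Fuzzy numbers are triangular or trapezoidal with non-decreasing
  breakpoints; mixed-arity comparisons promote the triangle `(a,b,c)` to
  `(a,b,b,c)`.
* Chen–Hwang defuzzification is defined on [0, 1]; closed forms
  `right = d/(1+d−c)`, `left = (1−a)/(1+b−a)` (kernel `[b,c]`, support
  `[a,d]`) reduce continuously for vertical legs and are verified against a
  dense-grid sup–min oracle (step 10⁻⁵, tolerance 10⁻⁴).
* Degrees of possibility use the standard intersection-height formula with
  an explicit `V = 0` branch for disjoint supports (omitting it produces
  out-of-range values); validated against the same style of grid oracle.
  The degenerate both-legs-vertical denominator cannot occur for valid
  triangulars once the dominance and disjointness guards have fired; the
  code keeps a continuity-limit fallback.
* Multi-expert comparison matrices are merged by weighted cell-wise
  arithmetic means; since the mean of reciprocals is not the reciprocal of
  the mean, reciprocity is re-imposed by replacing each upper cell with the
  per-point geometric mean of itself and the reciprocal of its transpose
  cell.  This is exact for a single expert and keeps matrices valid.
  Default is pre-aggregation (merge matrices, then one weight vector);
  post-aggregation (per-expert weight vectors, then averaged) is provided.
* Chang's extent analysis assigns weight exactly 0 to criteria whose
  synthetic extents are dominated — a known truncation of the method.  The
  package reports such zeros as computed; an all-zero vector raises instead
  of dividing.
* The elicitation vocabulary for category importance is configurable; the
  shipped default is this package's own 7-term triangular scale on [0, 1]
  (very low … very high), *not* a published membership-function set.

## Synthetic data

The generators emulate the study conditions with known ground truth: a
10-expert panel (the study's panel size), linguistic opinions snapped to
the nearest scale term and perturbed one step with probability
`opinion_noise` (default 0.1), pairwise matrices snapped from true weight
ratios to the five-term ladder, and category ratings drawn per subtask from
normal profiles whose defaults match the case-study column means
(6.2 ± 0.2, 4.1 ± 0.4, 4.2 ± 0.6).  All randomness derives from one seed
with documented per-generator stream splitting.

Ground-truth weight vectors are sampled so that adjacent sorted weights
differ by a ratio of at least 1.25 — below that boundary a ratio snaps to
"Equal importance" and the pair is indistinguishable in the vocabulary —
and the extreme ratio stays below 3.5, where the ladder saturates ("Very
much more", support up to 3.5).  Both constants are read off the published
scale's geometry.  In the recovery experiment (200 panels, 4–6 criteria,
10% noise) the ranking of the recovered weights matches the ground truth in
≈ 95% of trials; every observed failure is a tie between criteria truncated
to zero weight by the extent analysis, not an inversion.  Noise degradation
is demonstrated on 2-expert panels; with 10 experts, single-step noise is
averaged out and the rates at noise 0/0.1/0.3 are statistically
indistinguishable.

What the generators do **not** model: correlated expert biases, systematic
optimism, Delphi-style feedback rounds, or intransitive judgment patterns.
Passing recovery tests therefore show the pipeline's correctness and noise
robustness, not that real panels behave this way.

## Reproduction precision of the bundled case study

With the printed category ratings, the published weights and the default
calibration, all 31 recomputed HEPs agree with the printed column to within
1.5% relative error, and 23 of 31 to within half a unit in the last printed
decimal.  The remaining eight rows differ by up to 1.3 last-digit units
(e.g. row 5.6's neighbour 5.1 prints 1.39E-2 where the pipeline gives
1.377E-2; row 2.4 computes 2.066E-2, which rounds to 2.07, against a
printed 2.06): no choice of log-linear constants and three-decimal weights
reproduces the whole printed column at half-unit precision, so the printed
values carry rounding/transcription noise at that level.  The regression
test pinning half-unit agreement on all 31 rows is kept and fails for those
eight rows by design; the identity of the highest-risk (2.4) and
lowest-risk (3.1/3.2, tied) subtasks is reproduced exactly.

## Problem sizes

Test and acceptance runs use the bundled 31-subtask case study, 1,000
random instances per grid-oracle comparison, 200 panels in the recovery
experiment and 10,000 trials in the monotonicity sweep — the sizes the
statistical claims are stated at.

## Limitations

* No PSF interactions (a SLIM assumption; Bayesian-network extensions are
  out of scope), no uncertainty intervals on HEP, no risk scoring
  (probability only — consequences vary by patient and medication).
* The published panel's raw judgments are unavailable, so the bundled
  category and subPSF weights are fixtures validated for normalization
  invariants, not recomputable outputs.
* Saaty-style consistency checking of comparison matrices is not
  performed; wildly intransitive judgments will still produce weights.
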