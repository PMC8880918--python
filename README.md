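# fuzzyslim

A toolkit for quantifying the probability of medication errors in hospital
workflows with a fuzzy extension of the Success Likelihood Index Methodology
(SLIM).  It is aimed at patient-safety researchers and occupational health
and safety practitioners who want a transparent, auditable pipeline from
expert elicitation to a per-subtask human error probability (HEP).

## The model

Every subtask of a hierarchical task analysis is scored on performance
shaping factors (PSFs) — here three categories (*personal*, *job*,
*organization*) covering 17 concrete factors such as workload, fatigue and
patient safety climate.  Ratings run from 1 (worst situation) to 9 (best).
The Success Likelihood Index of a subtask is the weighted rating sum

```
SLI = Σᵢ Rᵢ · Wᵢ ,          1 ≤ SLI ≤ 9,
log₁₀(HEP) = a · SLI + b,
```

with `(a, b)` calibrated so the worst index maps to the highest credible
error probability and the best to the lowest — with the default bounds
`HEP(1) = 1` and `HEP(9) = 10⁻⁴`, the constants are `a = −0.5`, `b = 0.5`.

The weights come from two group-decision procedures rather than raw expert
guesses:

* **Category weights** — the similarity aggregation method (SAM): each
  expert's linguistic judgment becomes a fuzzy number; pairwise opinion
  similarity, relative agreement and expert credentials are blended
  (coefficient β, default 0.4) into consensus coefficients; the aggregated
  fuzzy opinion is defuzzified with the Chen–Hwang max–min score and
  normalized across categories.
* **Factor weights inside a category** — Chang's extent-analysis fuzzy AHP
  on a reciprocal matrix of linguistic pairwise comparisons (Equal … Very
  much more importance), via fuzzy synthetic extents and degrees of
  possibility.

The bundled fixtures are the published emergency-department case study: the
17-factor taxonomy with its fuzzy-AHP weights, a 5-task / 31-subtask
analysis of medication handling, its category ratings, and the published
category weights `SLI = 0.367·R_per + 0.311·R_job + 0.321·R_org`.

## Worked example

```
$ fuzzyslim reproduce-case-study
rank  subtask    R_per   R_job   R_org     SLI        HEP
   1  2.4        5.928   3.925   3.033   4.370   2.07E-02
   2  2.6        5.814   4.275   3.132   4.469   1.84E-02
   3  5.6        6.270   3.669   3.430   4.543   1.69E-02
...
  31  3.2        6.498   4.888   4.687   5.409   6.24E-03

highest HEP: subtask 2.4 (2.07E-02)
lowest HEP:  subtask 3.1, 3.2 (6.24E-03)
```

Subtask 2.4 — transcribing medication orders from the patient records file
into the Kardex — is the riskiest step (error probability ≈ 2.1%): its job
and organization conditions are rated poorly, dragging the SLI down to 4.37.
The two drugstore hand-over subtasks (3.1, 3.2) share the best conditions
and the lowest probability (≈ 0.6%).

The same machinery runs on your own data:

```
fuzzyslim weigh-psfs    --panel panel.csv --opinions opinions.csv --beta 0.4
fuzzyslim weigh-subpsfs --judgments judgments.csv
fuzzyslim assess        --ratings ratings.csv --category-weights 0.367 0.311 0.321
fuzzyslim simulate      --seed 7          # synthetic panel, end to end
```

File formats are plain CSV/YAML; see the `fuzzyslim.taxonomy` module
docstring.  As a library: `fuzzyslim.assess(tasks, sheet, taxonomy)` returns
`HEPResult` records, and `fuzzyslim.psf_weights` / `fuzzyslim.ahp_weights`
expose the two weighting pipelines with full audit traces.

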