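# Methods

## Similarity model

Global similarity between a query patient Q and a stored case C is the
weight-normalised sum of per-attribute local similarities,
sim(Q, C) = Σᵢ wᵢ·simᵢ(qᵢ, cᵢ) / Σᵢ wᵢ. Properties that follow directly
and are enforced by tests: scores lie in [0, 1]; identical complete records
score 1 (all shipped local functions are reflexive); rescaling all weights
by a common positive factor changes nothing.

**Missing values.** Attributes absent (or null) in either record are
dropped from numerator *and* denominator. This renormalisation keeps
partially observed records comparable on the attributes they share and is
the standard convention in CBR similarity amalgamation; the alternative
(scoring missing attributes 0) would conflate "unknown" with "maximally
dissimilar". A query and case with *no* shared attribute have no defined
similarity and raise an error rather than returning a default.

**Local functions.** Two families:

* `NumericDifference(plateau_width, anchors)` — similarity depends only on
  |q − c|. Differences up to `plateau_width` (units of the attribute; set to
  the instrument's minimal clinically important difference where one is
  established, e.g. 2 NRS points for pain intensity) score 1.0. Beyond the
  plateau, similarity interpolates piecewise-linearly through the ordered
  `(difference, similarity)` anchors and stays at the last anchor's value
  (the floor) for larger differences. Piecewise-linear is the simplest
  monotone shape that can express a non-linear decay; anchors must be
  strictly increasing in difference and non-increasing in similarity.
* `PairTable(table)` — explicit similarity per value pair, for ordinal and
  categorical attributes. Tables are symmetric by default (each unordered
  pair listed once; an explicit reverse entry can override this, but the
  shipped schema is fully symmetric since nothing suggests directional
  similarity); the diagonal is implicitly 1.0. Tables support
  position-dependent similarity — in the default schema 0 vs 1 activity
  day/week scores 0.4 while 5 vs 6–7 days scores 1.0.
  A `partial=True` table may cover only selected pairs; uncovered pairs
  raise a domain error. This exists for the worked-example fixture, which
  defines the sleep table only on the value pairs the example exhibits.

**Precision and display.** All comparisons and rankings use full double
precision; the 2-decimal scores seen in worked examples and the 4-decimal
CLI output are display rounding only.

**Default schema.** `data/default_model.yaml` ships 29 attributes over four
domains (sociodemographic; pain and function; psychological; health
behaviour). Five of them — mental distress (HSCL-10, weight 8),
expectations (4), pain sites (2), sleep problems (4), work ability (4) —
reproduce the published worked example exactly, and mental distress carries
the maximum weight, reflecting emotional distress as the key modifiable
prognostic factor. The full clinical attribute list and its weights are not
publicly deposited, so the remaining 24 attributes, their weights and their
local profiles are this package's own MCID-plus-consensus defaults; the
whole schema is an editable config, not code.

## Case base and outcome criterion

Cases carry baseline attribute values, region, ÖMSPQ (0–100) and MSK-HQ
(0–56) totals, a free-text treatment description, and an optional 3-month
follow-up (pain NRS, PSFS function, MSK-HQ, global perceived effect).
The exact published combined success criterion is not publicly deposited;
the default here is MCID-anchored in the same spirit and fully
parameterised:

    success = (pain improvement ≥ 2 NRS  OR  pain_3m ≤ 2)
              AND (MSK-HQ change ≥ 6  OR  GPE ≥ "much improved")

GPE uses the common 7-point scale (1 = very much worse … 7 = completely
recovered); "much improved" = 6. The rule is monotone: improving any single
follow-up measure never turns a success into a failure. Cases without
follow-up stay in the case base for plain retrieval (which needs only
baseline attributes) but are excluded — and counted — by the
successful-outcome filter, since "not evaluable" is not "failed".

## Retrieval

Exhaustive comparison and full sort; case bases here are hundreds of cases,
so sub-linear indexing would add complexity without benefit. Ties in score
are broken lexicographically by case id, making rankings deterministic and
insertion-order independent. A stored case with the query's own id is
excluded, which is exactly what leave-one-out evaluation and a retained
patient re-querying require.

## Evaluation harness

`leave_one_out_ranks` queries every case against the rest (n rankings of
length n − 1) using a vectorised pairwise-similarity matrix: numeric
attributes evaluate the plateau-plus-anchors profile on the full
|difference| matrix via linear interpolation; tabulated attributes index a
dense lookup by value code. The matrix path equals the scalar amalgamation
to 1e-12 (tested), and rankings are cross-checked against an independent
score-then-sort loop.

`rank_difference_curve` reports, per rank r, the mean over queries of
|instrument(query) − instrument(r-th neighbour)| with a two-sided 95%
Student-t interval (the bootstrap percentile interval is available as an
option; with ~100 queries per rank the two agree closely, and nothing
favours one over the other here). Ranks inherit the retrieval tie-break; no
fractional ranks. Degenerate inputs: identical patients give mean 0 with a
zero-width interval; fewer than two queries raise an error.

`compare_case_bases` computes per-rank mean similarity (leave-one-out
within each base) for a small and a large case base. With more candidate
neighbours the best matches can only get closer in distribution, so the
larger base is expected to win at rank 1.

## Synthetic cohort generator

The generator defines the study conditions for all evaluation; it emulates
a primary-care musculoskeletal cohort, not any particular patient set.

* **Marginals** follow the published descriptive table where available:
  age 46.0 (SD 15.2), 73.3 % women, BMI 26.9 (6.1), 56.2 % higher
  education, 82.9 % pain > 3 months, 8.6 % smokers, pain intensity 4.7
  (2.1), PSFS 4.0 (2.7), work ability 6.2 (2.9), risk groups
  41.6/46.5/11.9 %, region mix 15–22 % per region, MSK-HQ 37.7 (8.5),
  ÖMSPQ 43.1 (15.6). The remaining attributes use plausible primary-care
  values chosen once (e.g. sleep hours 7.0 ± 1.2, 60 % with previous
  episodes).
* **Mechanism.** One latent severity s ~ N(0, 1) per patient. Each
  attribute draws z = λ·s + √(1 − λ²)·ε and maps z monotonically to its
  marginal: location/scale plus clamping (and integer rounding for
  integer scales) for numeric attributes, Gaussian-quantile thresholding at
  the category probabilities for ordinal/categorical ones (labels ordered
  worst-last, so the category index rises with severity). Loadings λ are
  assumptions — the true attribute covariance is unpublished — signed so
  that "good" scales (function, work ability, expectations, self-efficacy)
  load negatively, with the heaviest prognostic attributes (mental distress
  0.7, risk group 0.7, pain/function 0.5–0.6) loading strongest.
* **Instruments.** ÖMSPQ = 43.1 + 13·s + N(0, 8²) clamped to [0, 100]
  (SD ≈ √(13² + 8²) ≈ 15.3, matching the target 15.6); MSK-HQ =
  37.7 − 7·s + N(0, 4.8²) rounded and clamped to [0, 56] (SD ≈ 8.5).
  Severity raises ÖMSPQ and lowers MSK-HQ, so the two are negatively
  correlated, as they are clinically.
* **Outcomes.** Follow-up improvements are linear in −s with noise
  (pain change 2.2 − 1.2 s ± 1.5, function 2.0 − 1.0 s ± 1.5, MSK-HQ
  change 6.5 − 3 s ± 4; GPE thresholds a 1.5 − 0.8 s ± 1 latent), so the
  success probability decreases with severity — roughly 55–60 % of the
  default cohort succeeds.
* **Determinism.** One integer seed drives a single `numpy` Generator;
  identical recipes give bit-identical cohorts and files.

**What passing tests show — and don't.** Because the instruments and the
attributes share the latent factor, nearest neighbours under the similarity
model are also close on ÖMSPQ/MSK-HQ, reproducing the qualitative rising
rank-difference curve and the case-base-size effect. A zero-loading cohort
(loading_scale = 0) is the negative control: attributes and instruments are
then independent and the curve is flat. The generator is single-factor with
conditionally independent attributes and no item-level overlap between the
attribute set and the questionnaires; real cohorts have richer covariance,
informative missingness and measurement quirks none of which are modelled.
Synthetic results therefore validate the *machinery* (correct amalgamation,
ranking, curves) and the *direction* of the published findings, not their
magnitudes: published real-cohort numbers (e.g. rank-1 mean differences of
9.3 ÖMSPQ / 5.6 MSK-HQ points) depend on undeposited data and are not
reproduction targets.

## Problem sizes and statistical checks

The stochastic suites use 20 cohorts (seeds 0–19): shape recovery requires
Spearman ρ > 0 with p < 0.01 between rank and mean |ΔÖMSPQ| in every seed
(n = 105); the flat negative control requires rank-1 and last-rank means
within 2 pooled standard errors in ≥ 16/20 seeds (each seed passes with
≈ 95 % probability under independence, so ≥ 16/20 fails with < 0.2 %
probability); the case-base-size effect requires the nested 486-patient
base to beat its 105-patient subset on rank-1 mean similarity in ≥ 18/20
seeds. Oracle-equivalence checks run at n = 50, exact to 1e-12.

## Known limitations

* The 24 non-published attributes, their weights, local profiles and the
  generator loadings are defaults, not estimates; treat them as a starting
  schema to edit.
* Single-factor generation cannot express attribute clusters (e.g.
  psychological attributes more correlated with each other than with BMI).
* Treatment descriptions are labels drawn at random; the package does not
  model treatment content or effects, and the reuse/revise (adaptation)
  steps of the CBR cycle — clinician judgement — are out of scope.
* Asymmetric local similarity is representable in a `PairTable` but unused
  by the shipped schema.
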