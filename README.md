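# mskcbr

Case-based reasoning (CBR) patient-similarity retrieval for musculoskeletal
pain cohorts in primary care.

Treatment guidelines for musculoskeletal pain carry group-level evidence
that transfers poorly to the heterogeneous patients clinicians actually
see. A CBR decision-support system sidesteps this by retrieving the *most
similar past patients* to a new one and showing which treatments worked for
those of them with a successful outcome. `mskcbr` implements the retrieval
core of such a system — the similarity model, the case base with its
successful-outcome filter, ranked retrieval, and the leave-one-out
evaluation harness — plus a seeded synthetic-cohort generator that emulates
a primary-care musculoskeletal cohort, since real cohorts of this kind are
not publicly deposited.

## The model

Similarity follows the local-global principle. Each clinical attribute
*i* (pain intensity, mental distress, sleep problems, ...) has a **local
similarity** function sim<sub>i</sub>(q, c) ∈ [0, 1] between the query's
value q and a stored case's value c, and a positive **weight**
w<sub>i</sub> (integers 1–8, higher = more prognostically relevant). The
**global (amalgamated) similarity** is the weighted mean

```
sim(Q, C) = Σᵢ wᵢ · simᵢ(qᵢ, cᵢ) / Σᵢ wᵢ
```

so scores live in [0, 1], with 1 meaning full conformity. Numeric local
functions plateau at 1.0 inside the attribute's minimal clinically
important difference (MCID — e.g. 2 points on the pain NRS) and decay
piecewise-linearly beyond it; ordinal attributes use pair tables that can
be position-dependent (0 vs 1 activity day/week is only 0.4 similar, while
5 vs 6–7 days is fully similar). A 29-attribute default schema covering
sociodemographic, pain/function, psychological and health-behaviour
domains ships as an editable YAML config, with mental distress (HSCL-10)
carrying the maximum weight 8.

Retrieval compares the query exhaustively against every case and ranks by
descending similarity (ties broken by case id). The *successful-only*
variant first filters the case base by a combined 3-month outcome
criterion — by default (pain improvement ≥ 2 NRS points OR 3-month
pain ≤ 2) AND (MSK-HQ change ≥ 6 OR global perceived effect at least
"much improved") — and returns each hit's treatment description.

The evaluation harness queries every patient against the rest
(leave-one-out) and plots, per rank, the mean absolute difference (95% CI)
between the query's and the neighbour's score on two external instruments:
the Örebro Musculoskeletal Pain Screening Questionnaire (ÖMSPQ, 0–100,
higher = worse prognosis) and the Musculoskeletal Health Questionnaire
(MSK-HQ, 0–56, higher = better health). A curve that rises with rank means
nearest neighbours are genuinely closer clinically.

## Worked example

`examples/01_worked_similarity_example.py` reproduces the five-attribute
worked calculation (weights 8, 4, 2, 4, 4; total weight 22):

```
patient   total similarity
A          20.4       0.93
B          19.2       0.87
C          16.0       0.73
D          13.6       0.62
ranking: A > B > C > D
```

Patient A's weighted local similarities sum to 20.4 of a possible 22:
amalgamated similarity (8·0.8 + 4·1.0 + 2·1.0 + 4·1.0 + 4·1.0)/22 ≈ 0.93,
the best match. The other examples retrieve successful similar patients
with their treatments, trace the leave-one-out rank curve (on the default
seeded cohort: rank-1 mean |ΔÖMSPQ| ≈ 12.0 rising to ≈ 33.9 at the last
rank, Spearman ρ = 0.91), and show that a 486-patient case base retrieves
closer neighbours than its nested 105-patient subset at every rank.

There is also a thin CLI:

```sh
mskcbr simulate --n 105 --seed 1 --out cases.csv
mskcbr retrieve --casebase cases.csv --query query.json -k 10 --successful-only
mskcbr evaluate --casebase cases.csv --instrument omspq
```

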