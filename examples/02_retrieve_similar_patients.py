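"""Retrieve successfully treated similar patients for a new query.

Generates a seeded synthetic 105-patient cohort, takes the first patient
as the new (query) patient, and retrieves the 5 most similar of the
*remaining* patients whose 3-month outcome met the combined success
criterion — their treatments are what a clinician would be shown.
"""

import mskcbr as m

model = m.default_model()
cohort = m.generate_cohort(m.default_cohort_model(n=105, seed=1))
query, rest = cohort.cases[0], m.CaseBase(cases=cohort.cases[1:])

crit = m.SuccessCriterion()
successful = m.filter_successful(rest, crit)
print(f"case base: {len(rest)} patients, {len(successful)} with successful outcomes")

res = m.retrieve_successful(model, rest, query, crit, k=5)
print(f"query {res.query_id}: ÖMSPQ {query.omspq:.0f}, MSK-HQ {query.mskhq_baseline}")
print(f"{'rank':<5} {'case':<9} {'score':>6}  treatment")
for i, ((cid, score), treatment) in enumerate(zip(res.ranking, res.treatments), 1):
    print(f"{i:<5} {cid:<9} {score:>6.4f}  {treatment}")
print("Each hit is a past patient similar to the query whose outcome was "
      "successful; their treatments inform the new patient's plan.")
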