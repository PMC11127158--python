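"""Leave-one-out rank evaluation against the ÖMSPQ instrument.

Every patient in a seeded 105-patient synthetic cohort is queried against
the rest; at each rank r the mean absolute ÖMSPQ difference between query
and r-th most similar neighbour is computed with a 95% t-interval. A curve
that rises with rank means the similarity model's nearest neighbours really
are clinically closer than distant ones.
"""

import mskcbr as m

model = m.default_model()
cohort = m.generate_cohort(m.default_cohort_model(n=105, seed=1))

rankings = m.leave_one_out_ranks(model, cohort)
curve = m.rank_difference_curve(rankings, cohort, "omspq")

print("rank  mean |dOMSPQ|  95% CI          n")
for r, mean, lo, hi, n in curve.per_rank[:5]:
    print(f"{r:>4}  {mean:>12.1f}  ({lo:.1f}-{hi:.1f})  {n}")
last = curve.per_rank[-1]
print(f"{last[0]:>4}  {last[1]:>12.1f}  ({last[2]:.1f}-{last[3]:.1f})  {last[4]}  (least similar)")

rho, p = m.rank_trend(curve)
print(f"Spearman rank-vs-difference: rho={rho:.2f}, p={p:.1e}")
print("The rank-1 mean is far below the last-rank mean: the most similar "
      "patients score closest to the query on the screening instrument.")
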