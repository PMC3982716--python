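"""Simulate a Ct-level cohort and recover the group structure end to end.

Draws a 10+6 cohort with a 4-cycle hypermethylator shift on every panel
miR, pushes it through quantification, threshold fitting and scoring,
and correlates the miR score with the simulated methylation/expression
scores.
"""

import mirscore as ms
from mirscore.synthetic import SyntheticConfig, simulate_cohort

cohort = simulate_cohort(SyntheticConfig(seed=1))
expr = ms.relative_expression(cohort.ct_table)
rq = expr.rq.loc[cohort.labels.index]
labels = cohort.labels.to_numpy()

models = [
    ms.fit_threshold(rq[m].to_numpy(), labels, marker_id=m)
    for m in cohort.config.markers
]
print("fitted CA per marker (1.0 = perfect separation):")
for m in models:
    print(f"  {m.marker_id:9s} CA = {m.metrics.ca:.2f}")

scores = ms.mir_scores(ms.make_calls(rq, models))
merged = cohort.sample_scores.join(scores)
expr_res, meth_res = ms.score_associations(merged)
print(
    f"\nmiR score vs expression score:  r = {expr_res.r:+.2f} (p = {expr_res.p_value:.1e})"
    f"\nmiR score vs methylation score: r = {meth_res.r:+.2f} (p = {meth_res.p_value:.1e})"
)
print(
    "A 4-cycle Ct shift is a 16-fold expression drop, so every marker "
    "separates the groups; the score correlations recover the simulated "
    "signs (negative for expression, positive for methylation)."
)
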