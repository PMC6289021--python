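"""Deterministic base case: which prophylaxis strategy buys the most health
per pound after an elective hip replacement?

Loads the packaged eTHR parameter set, runs every strategy through the
90-day decision tree and the lifetime Markov model, and prints the
cost-effectiveness table: discounted QALYs and costs per person, incremental
net monetary benefit (INMB) vs the comparator (LMWH standard dose/duration
plus anti-embolism stockings) at £20,000 per QALY, and the NMB ranking.
A positive INMB means the strategy is better value than the comparator.
"""

from vtecea import evaluate_population, load_inputs

inputs = load_inputs(population="eTHR")
result = evaluate_population(inputs)

table = result.summary_table()[["qalys", "cost", "inmb", "status", "rank"]]
print(table.round(3).sort_values("rank").to_string())

best = result.ce.best
print(
    f"\nMost cost-effective at £{result.ce.lam:,.0f}/QALY: "
    f"{inputs.strategy(best).label} "
    f"(INMB £{result.ce.table.loc[best, 'inmb']:,.0f} vs comparator)"
)
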