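"""Acute-phase event tallies: expected events per 1,000 knee-replacement
patients in the first 90 days, by prophylaxis strategy.

The decision tree combines VTE, major-bleeding, CRNMB/infection and HIT
outcomes under the rule that only one symptomatic event occurs per person.
Each row prints symptomatic and asymptomatic DVT, non-fatal PE, total VTE,
surgical-site bleeds and acute deaths per 1,000; PTS and CTEPH columns are
lifetime sequelae counts from the Markov phase.  The comparator row matches
the published outcome table (144 total VTE, 134 asymptomatic DVT per 1,000).
"""

from vtecea import evaluate_population, load_inputs

inputs = load_inputs(population="eTKR")
result = evaluate_population(inputs)

print(result.tallies_table(rounded=True).to_string())
comp = result.outcomes[inputs.comparator]
print(
    f"\nComparator ({inputs.strategy(inputs.comparator).label}): "
    f"{comp.acute.rounded_tallies['total_vte']} VTE events per 1,000, "
    f"acute cost £{comp.acute.acute_cost:,.0f} per person."
)
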