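# vtecea

Cost-utility modelling of venous-thromboembolism (VTE) prophylaxis after
elective total hip (eTHR) and total knee (eTKR) replacement, from the English
NHS perspective.

Hip and knee arthroplasty carry a high risk of hospital-acquired VTE — deep
vein thrombosis (DVT) or pulmonary embolism (PE) — but pharmacological
prophylaxis trades that risk against bleeding, wound complications and cost.
This package compares 16 prophylaxis strategies for eTHR and 13 for eTKR
(mechanical devices, low-molecular-weight heparin regimens, DOACs, aspirin,
combinations, and no prophylaxis), for health economists and guideline
analysts who need a transparent, testable implementation of this class of
decision model.

## Model

* A **90-day decision tree** combines four event processes per strategy:
  VTE (asymptomatic/symptomatic, distal/proximal DVT, non-fatal/fatal PE),
  major bleeding (surgical site → return to theatre; GI ± intervention;
  intracranial haemorrhage → permanent disability; other; fatal),
  clinically-relevant non-major bleeding (→ wound haematoma → surgical-site
  infection → medical/surgical management), and heparin-induced
  thrombocytopenia (success/thrombosis/major bleed/death, with an amputation
  fraction).  Only one symptomatic event is allowed per person; joint
  occurrences are resolved by a strict priority ranking
  (fatal > PE > symptomatic DVT > major bleed > CRNMB) in closed form.
* A **lifetime annual-cycle Markov cohort model** from day 90 tracks
  post-thrombotic syndrome (PTS, mild-moderate/severe, onset in the first
  two years), chronic thromboembolic pulmonary hypertension (CTEPH, with
  20% first-year mortality), post-stroke disability, post-HIT amputation and
  post-revision states, with tunnel states for first-year costs and
  age-indexed all-cause mortality.  Rate↔probability conversions use
  r = −ln(1−P)/t and P = 1 − e^(−rt).
* **Valuation**: EQ-5D utilities on a linear recovery trajectory
  (pre-operative value rising to the 9-month value), event-based
  disutilities from day 7 (day 21 for PE), 2016 GBP costs, 3.5% discounting
  beyond the first year.
* **Decision rule**: net monetary benefit NMB(X) = QALYs(X)·λ − Costs(X) at
  λ = £20,000/QALY; dominance and extended dominance define the ICER
  frontier; probabilistic sensitivity analysis (PSA) yields the probability
  each strategy is the most cost-effective and CEAC curves.

Parameter tables for both populations ship as packaged CSV fixtures; a
synthetic-data module generates life tables and random-but-valid parameter
sets for testing.

## Worked example

```python
from vtecea import evaluate_population, load_inputs

inputs = load_inputs(population="eTHR")
result = evaluate_population(inputs)
print(result.summary_table()[["qalys", "cost", "inmb", "status", "rank"]]
      .round(3).sort_values("rank").head())
```

```
                   qalys      cost       inmb        status  rank
strategy
lmwh_aspirin       7.506   444.849    495.103  nondominated     1
aes                7.485   364.430    158.061  nondominated     2
lmwh_std_extd_aes  7.503   824.944     55.109     dominated     3
lmwh_std_std_aes   7.493   688.881      0.000     dominated     4
foot_pump_aes      7.479   462.412    -61.518     dominated     5
```

Each row is one strategy's lifetime discounted QALYs and costs per person.
`inmb` is the incremental net monetary benefit at £20,000/QALY against the
model comparator, LMWH (standard dose, standard duration) + anti-embolism
stockings: LMWH for 10 days followed by low-dose aspirin for 28 days is
worth about £495 more per patient than the comparator and ranks first, the
same ordering the probabilistic analysis gives.  For the knee population the
foot pump ranks first, followed by aspirin.

The `examples/` directory has one short script per capability (base case,
acute-event tallies, PSA, scenario analysis, synthetic inputs), and the
`vtecea` CLI (`run-base-case`, `run-psa`, `scenario`, `make-fixtures`)
writes the same analyses as CSV with a reproducibility manifest.

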