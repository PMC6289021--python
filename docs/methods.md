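# Methods

## Model structure and assumptions

The model is a 90-day decision tree chained to a lifetime annual-cycle
Markov cohort model, run separately for the elective hip (eTHR) and knee
(eTKR) populations with identical structure and population-specific inputs.

Key behavioural assumptions, all carried from the source analysis:

* Asymptomatic DVT is not diagnosed: it incurs no acute cost or disutility,
  but it does carry long-term PTS risk through its own Markov entry states.
* Only one symptomatic event occurs per person in the acute window. The
  four event processes (VTE, major bleeding, CRNMB chain, HIT chain) are
  combined as independent hazards and joint occurrences resolved by a strict
  global priority ranking — fatal events, then PE, then symptomatic DVT,
  then major bleeding, then CRNMB — with the suppressed event's mass
  reassigned to the surviving event. Because the arms are independent, the
  resolved probability of each outcome has a closed form (its marginal
  probability times, per other arm, the probability of a strictly
  lower-priority outcome); tests verify exact agreement with brute-force
  joint enumeration. Asymptomatic DVT is never suppressed, so its expected
  counts remain marginal.
* Treatment of symptomatic proximal DVT and PE (50% DOAC, 50%
  LMWH+warfarin, embedded in the event costs) is 100% effective with no
  recurrence; long-term progression is treatment-independent.
* ICH/haemorrhagic stroke causes permanent disability; surgical-site major
  bleeding always returns to theatre; GI bleeds need intervention in 13% of
  cases; SSI surgical management splits 1:1 between revision and return to
  theatre.
* PE case fatality (17%) converts the printed **non-fatal** PE risk:
  fatal = non-fatal × 0.17/0.83. The alternative reading (17% of all PE) is
  available as `TreeConfig.pe_fatality_mode="of_all"`.

## Markov phase

States: well; five post-VTE states; PTS mild-moderate/severe year-1 tunnels
and chronic states; CTEPH year-1, recurrent-year-2 (both tunnels), chronic
and treated states; disabled post-stroke; amputated post-HIT; post-revision
for infection; dead (absorbing). Cycle length one year; entry at age
start_age + 90/365.25; integer-age life-table lookup (nearest age).

* PTS onset is restricted to the first two cycles, with per-cycle
  probability p solving 1−(1−p)² = stated 2-year incidence per antecedent
  event, via the rate↔probability transforms.
* From the post-PE state PTS (15%/2y) and CTEPH (3.2%/2y) compete. The
  combined 2-year probability is converted to a per-cycle probability and
  split proportionally to the marginal incidences, so the two-cycle
  composition of each pathway reproduces its stated 2-year incidence
  exactly; a naive independent conversion under competition cannot, and the
  exactness is a tested invariant (±1e-9).
* CTEPH mortality (20%) applies once, during the year-1 tunnel, multiplied
  with background mortality; survivors split between a recurrent/resistant
  year-2 tunnel and a treated state (fraction recurrent is a package
  default, 1/3).
* Mortality is background-only in all other live states (no excess PTS,
  stroke or amputation mortality is specified).
* No half-cycle correction in the base case (the original is a spreadsheet
  cohort model); `MarkovConfig.half_cycle_correction` enables it, and the
  life-table expectation oracle is tested under both accrual conventions.

The Markov phase is treatment-independent, so per-cycle transition matrices
and state values are computed once per parameter set and contracted against
each strategy's entry distribution; equality with per-strategy cohort traces
is tested.

## Valuation

Baseline utility rises linearly from the pre-operative EQ-5D index at
surgery to the post-operative value anchored at 9 months (day 270), constant
thereafter. The printed post-operative anchors are 0.579 (eTHR) and 0.582
(eTKR); the pre-operative values are **package defaults** (0.355 / 0.400,
PROMS-like) because no pre-operative index is printed. Event disutilities
apply from day 7 (day 21 for PE) to day 90 — the windows are a package
default, consistent with recovery rejoining the post-operative trajectory —
with relative decrements multiplying the time-varying trajectory value,
absolute decrements subtracting from it, and a floor at −0.594. Fatal events
truncate accrual at the event day. Half the warfarin-monitoring decrement
(−0.012 × 50%) attaches to treated VTE events. Markov-phase baseline utility
averages the trajectory over days 90–455 in cycle 0 and uses the 9-month
value thereafter (an optional annual decrement, default 0, hooks in age
dependence). Post-revision and post-stroke states use relative decrements
(−30%, −10%); CTEPH year-2+ utility applies the +22% post-treatment
improvement multiplicatively to the year-1 value.

Costs are 2016 GBP as printed, never re-inflated. Other-site major bleeding
has no tabulated cost and is costed as medically-managed (GI
without-intervention) bleeding. Stroke and amputation state costs
distinguish year 1 from year 2+; the stroke dependent/independent mix (25%
dependent) and the CTEPH year-1 stratum weights (1/3 operable / inoperable /
recurrent) are package defaults, as are the HIT outcome split
(0.94/0.03/0.02/0.01), the HIT amputation probability (0.01), the fatal
major-bleeding probability (0) and the GI share of the combined GI+ICH risk
(0.5) — none of these is printed; all are config-overridable.

Discounting is 3.5%/year for costs and outcomes beyond the first year: the
acute phase and Markov cycle 0 are undiscounted and cycle k carries
(1+r)^−k.

## Comparator bleeding inputs

The baseline-risk table and the absolute-risk table disagree on the
comparator's bleeding rows (eTHR surgical-site 2.29% vs 0.94%; CRNMB 2.95%
vs 3.04%; analogous for eTKR). The base case uses the baseline table for the
comparator — its stated source is the single-arm meta-analysis — while
non-comparator strategies use the absolute-risk table as printed; both are
stored in the fixtures, so the alternative is a one-line override. The
comparator's surgical-site tally therefore does not reproduce the outcome
table's printed value (which matches neither source); the VTE tallies, which
are the reproduction targets, are unaffected.

## Probabilistic analysis

Families are package defaults (the source states only that the model was run
probabilistically): beta for probabilities, moment-matched from printed SEs,
from 95% interval widths, or from an SE of 20% of the mean when neither is
printed; gamma for event and state costs (SE 20% of mean; intervention unit
prices fixed); lognormal for relative effects with log-scale SD matched to
the printed credible intervals (risk ratios for DVT/PE against the sampled
baseline; odds ratios for bleeding against the comparator row, SD 0.2 as no
bleeding intervals are printed). Where a strategy's DVT or PE effect was
imputed from the other by proportionality, one standard-normal draw drives
both. Structural fractions are fixed. Lognormal draws are median-preserving
(point × exp(σZ)). Extreme draws that push DVT + PE (or the bleeding sum)
above 1 are capped proportionally and the iteration counted — with the very
wide printed intervals for mechanical-only and aspirin strategies this
affects a substantial minority of iterations, which is a faithful
consequence of those intervals rather than a numerical artefact.

Summaries use percentile (not normal-approximation) intervals; the
probability of being most cost-effective is the fraction of iterations with
the maximal NMB; CEACs are computed on a £0–50,000 grid. The default run is
10,000 iterations and finishes in under two minutes per population on one
CPU.

The published probabilistic means are not exactly reproducible because the
distribution families and several sub-tree probabilities are unpublished;
the package instead checks the published *ordering* statements (LMWH
followed by aspirin first for eTHR; at most three strategies worse than no
prophylaxis), which hold under these defaults.

## Synthetic data

The life table is a Gompertz–Makeham stand-in, q(x) = a + b·e^(cx) with
a = 1e-4, b = 1.8e-5, c = 0.0975 on ages 0–110 (terminal q = 1), calibrated
so life expectancy at 68.7 is ≈ 17.3 years — plausible for this cohort; real
life tables load from CSV (`age,qx`). The generator also produces random
internally-consistent parameter sets (lognormal effects around 1, ordered
utilities, uniform costs; always passing validation) and known-answer
dominance/frontier/ranking panels whose expected statuses are computed by
exhaustive brute force at generation time. Synthetic inputs emulate the
statistical *structure* of the real tables, not their clinical correlations
(e.g. no bleeding–efficacy trade-off), so passing tests on them establish
the engine's correctness, not clinical calibration.

## Numerical choices

Branch and entry-distribution conservation are asserted at 1e-10 internally
and tested at 1e-12; transition rows at 1e-12; day count 365.25/year;
per-1,000 tallies round half to even for report output with unrounded values
retained; report currency is integer GBP, machine outputs full precision.
Equal-cost, equal-QALY strategies dominate neither and both are retained;
NMB ties rank by lower cost, then name.

## Limitations

* Sensitivity analyses SA3, SA5, SA8–SA11 are hooks requiring user-supplied
  alternative inputs (none are printed); SA1, SA2, SA4, SA6, SA7 are fully
  parameterized.
* Absolute QALY levels depend on the unprinted pre-operative utility and on
  reading the printed utility anchors as 9-month values; rankings and
  incremental results, which drive every decision output, are insensitive
  to this common offset.
* HIT-thrombosis events are tallied under the HIT chain rather than the
  primary VTE counts (consistent with the printed per-1,000 tables).
* No patient-level simulation, no VTE recurrence, no value-of-information
  analysis.
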