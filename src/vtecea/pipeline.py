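"""End-to-end evaluation of one population: tree → Markov → valuation → CEA.

The Markov phase is treatment-independent, so its per-cycle transition
matrices and state values are computed once per parameter set and shared
across strategies: with A_k the k-step occupancy operator and d_k the cycle
discount factor, the vector V_q = Σ_k d_k A_k u_k gives each entry state's
discounted QALY yield per unit mass, and C = Σ_k d_k A_k diag(c_k) the
discounted cost by (entry state, accruing state).  Per-strategy totals are
then dot products with the acute model's entry distribution.  This is
algebraically identical to running the cohort trace per strategy (a tested
equivalence) and keeps a 10,000-iteration probabilistic analysis tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acute import AcuteResult, evaluate_acute, round_half_even
from .cea import CEResult, evaluate_strategies
from .markov import N_STATES, S, STATES, build_transition_matrix
from .types import ModelInputs
from .valuation import STATE_COST_CATEGORY, cycle_discount, state_value


@dataclass
class MarkovComponents:
    """Strategy-independent Markov aggregates (per unit entry mass)."""

    qaly_value: np.ndarray      # (n_states,) discounted QALYs by entry state
    cost_by_state: np.ndarray   # (n_states, n_states) discounted cost matrix
    pts_cases: np.ndarray       # (n_states,) expected PTS cases by entry state
    cteph_cases: np.ndarray     # (n_states,) expected CTEPH cases

    @property
    def cost_value(self) -> np.ndarray:
        return self.cost_by_state.sum(axis=1)


def markov_components(inputs: ModelInputs) -> MarkovComponents:
    entry_age = inputs.cohort.start_age + 90.0 / 365.25
    terminal = float(inputs.life_table.ages[-1])
    horizon = inputs.settings.time_horizon_years
    max_cycles = int(math.ceil(terminal - entry_age)) + 1
    if horizon is not None:
        if horizon < 1.0:
            raise ValueError("time horizon must cover at least one cycle")
        max_cycles = min(max_cycles, int(round(horizon)))

    rate = inputs.settings.discount_rate
    half = inputs.markov_config.half_cycle_correction
    a_k = np.eye(N_STATES)
    qaly_value = np.zeros(N_STATES)
    cost_by_state = np.zeros((N_STATES, N_STATES))
    pts_cases = np.zeros(N_STATES)
    cteph_cases = np.zeros(N_STATES)
    util_vec = np.empty(N_STATES)
    cost_vec = np.empty(N_STATES)
    i_pts = [S["pts_mildmod_y1"], S["pts_severe_y1"]]
    i_ct = S["cteph_y1"]
    i_dead = S["dead"]

    for k in range(max_cycles):
        age = entry_age + k * inputs.settings.cycle_length_years
        m = build_transition_matrix(inputs, k, age)
        a_next = a_k @ m
        basis = 0.5 * (a_k + a_next) if half else a_k
        for i, state in enumerate(STATES):
            util_vec[i], cost_vec[i] = state_value(state, k, inputs)
        d = cycle_discount(k, rate)
        qaly_value += d * (basis @ util_vec)
        cost_by_state += d * basis * cost_vec[np.newaxis, :]
        # tunnel residency is one cycle, so summed occupancy counts entrants
        pts_cases += a_next[:, i_pts].sum(axis=1)
        cteph_cases += a_next[:, i_ct]
        a_k = a_next
        if a_k[:, i_dead].min() > 1.0 - 1e-12:
            break
    return MarkovComponents(qaly_value, cost_by_state, pts_cases, cteph_cases)


@dataclass
class StrategyOutcome:
    strategy: str
    acute: AcuteResult
    total_qalys: float
    total_cost: float
    markov_qalys: float
    markov_cost: float
    pts_per_1000: float
    cteph_per_1000: float
    cost_breakdown: dict


@dataclass
class PopulationResult:
    inputs: ModelInputs
    outcomes: dict[str, StrategyOutcome]
    ce: CEResult

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for name, oc in self.outcomes.items():
            row = {"strategy": name, "qalys": oc.total_qalys, "cost": oc.total_cost}
            rows.append(row)
        df = pd.DataFrame(rows).set_index("strategy")
        return df.join(self.ce.table[["inc_qalys", "inc_cost", "nmb", "inmb",
                                      "status", "icer", "rank"]])

    def tallies_table(self, rounded: bool = True) -> pd.DataFrame:
        cols = ["sympt_dvt", "sympt_prox_dvt", "asympt_dvt", "nonfatal_pe",
                "total_vte", "ssb_return_to_theatre", "deaths"]
        rows = {}
        for name, oc in self.outcomes.items():
            t = oc.acute.tallies_per_1000
            row = {c: t.get(c, 0.0) for c in cols}
            row["pts"] = oc.pts_per_1000
            row["cteph"] = oc.cteph_per_1000
            if rounded:
                row = {c: round_half_even(v) for c, v in row.items()}
            rows[name] = row
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("strategy")

    def cost_breakdown_table(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            {n: oc.cost_breakdown for n, oc in self.outcomes.items()},
            orient="index",
        ).rename_axis("strategy")


def _entry_array(entry: dict[str, float]) -> np.ndarray:
    v = np.zeros(N_STATES)
    for state, p in entry.items():
        v[S[state]] += p
    return v


def evaluate_population(inputs: ModelInputs, lam: float | None = None) -> PopulationResult:
    """Deterministic (point-estimate) run of the full model for all strategies."""
    comp = markov_components(inputs)
    lam = inputs.settings.threshold_lambda if lam is None else lam
    outcomes: dict[str, StrategyOutcome] = {}
    for strategy in inputs.strategy_names:
        acute = evaluate_acute(inputs, strategy)
        entry = _entry_array(acute.entry_distribution)
        mk_q = float(entry @ comp.qaly_value)
        state_costs = entry @ comp.cost_by_state
        mk_c = float(state_costs.sum())
        breakdown = _breakdown(acute, state_costs, inputs)
        outcomes[strategy] = StrategyOutcome(
            strategy=strategy,
            acute=acute,
            total_qalys=acute.acute_qalys + mk_q,
            total_cost=acute.acute_cost + mk_c,
            markov_qalys=mk_q,
            markov_cost=mk_c,
            pts_per_1000=float(entry @ comp.pts_cases) * 1000.0,
            cteph_per_1000=float(entry @ comp.cteph_cases) * 1000.0,
            cost_breakdown=breakdown,
        )
    names = inputs.strategy_names
    ce = evaluate_strategies(
        names,
        [outcomes[n].total_qalys for n in names],
        [outcomes[n].total_cost for n in names],
        lam,
        inputs.comparator,
    )
    return PopulationResult(inputs=inputs, outcomes=outcomes, ce=ce)


def _breakdown(acute: AcuteResult, state_costs: np.ndarray, inputs: ModelInputs) -> dict:
    from .params import strategy_total_cost
    from .valuation import ACUTE_COST_CATEGORY, acute_event_costs

    out = {"prophylaxis": strategy_total_cost(acute.strategy, inputs.costs),
           "vte": 0.0, "bleeding": 0.0, "cteph": 0.0, "pts": 0.0,
           "post_amputation": 0.0}
    unit = acute_event_costs(inputs)
    for kind, p in acute.branch_table.items():
        if p > 0.0 and unit[kind]:
            out[ACUTE_COST_CATEGORY[kind]] += p * unit[kind]
    for i, state in enumerate(STATES):
        if state_costs[i] and state in STATE_COST_CATEGORY:
            out[STATE_COST_CATEGORY[state]] += float(state_costs[i])
    return out


def totals_for_strategies(inputs: ModelInputs) -> tuple[np.ndarray, np.ndarray]:
    """(qalys, costs) arrays over the strategy panel — the PSA inner loop."""
    comp = markov_components(inputs)
    names = inputs.strategy_names
    qalys = np.empty(len(names))
    costs = np.empty(len(names))
    for j, strategy in enumerate(names):
        acute = evaluate_acute(inputs, strategy)
        entry = _entry_array(acute.entry_distribution)
        qalys[j] = acute.acute_qalys + float(entry @ comp.qaly_value)
        costs[j] = acute.acute_cost + float(entry @ comp.cost_value)
    return qalys, costs
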