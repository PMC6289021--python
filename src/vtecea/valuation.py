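"""Valuation: utilities, disutilities, costs and discounting.

Quality of life follows a piecewise-linear recovery trajectory: the
pre-operative EQ-5D index at surgery rising linearly to the post-operative
value anchored at 9 months (day 270), constant thereafter.  Acute events
interrupt the trajectory from their event day (day 7 for DVT, bleeding and
other adverse events; day 21 for PE) to day 90; relative decrements multiply
the time-varying trajectory value, absolute decrements subtract from it, and
utilities are floored at the EQ-5D minimum of −0.594.

Discounting follows the reference-case convention of 3.5% per year for
costs and outcomes accrued beyond the first year: the acute phase and the
first Markov cycle are undiscounted, and Markov cycle k carries the factor
(1+r)^−k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .types import DAYS_PER_YEAR, EQ5D_FLOOR, ModelInputs, UtilitySet

ACUTE_WINDOW_DAYS = 90.0
TRAJECTORY_ANCHOR_DAY = 270.0  # 9 months


@dataclass(frozen=True)
class UtilityTrajectory:
    """Linear recovery from the pre-operative utility to the 9-month value."""

    preop: float
    value_at_9mo: float

    def value(self, day: float) -> float:
        if day < 0:
            raise ValueError("day must be >= 0")
        frac = min(day, TRAJECTORY_ANCHOR_DAY) / TRAJECTORY_ANCHOR_DAY
        return self.preop + (self.value_at_9mo - self.preop) * frac

    def integral(self, day0: float, day1: float) -> float:
        """∫ utility dt over [day0, day1], in utility·days (exact)."""
        if day1 < day0:
            raise ValueError("day1 must be >= day0")
        total = 0.0
        # linear part up to the anchor, constant after
        a, b = day0, min(day1, TRAJECTORY_ANCHOR_DAY)
        if b > a:
            total += (self.value(a) + self.value(b)) / 2.0 * (b - a)
        if day1 > TRAJECTORY_ANCHOR_DAY:
            total += self.value_at_9mo * (day1 - max(day0, TRAJECTORY_ANCHOR_DAY))
        return total


def baseline_utility(day: float, trajectory: UtilityTrajectory) -> float:
    """Baseline (no-event) utility on a given post-operative day."""
    return trajectory.value(day)


def trajectory_from(utilities: UtilitySet) -> UtilityTrajectory:
    return UtilityTrajectory(preop=utilities.preop, value_at_9mo=utilities.post_9mo)


def discount_factor(t_years: float, rate: float) -> float:
    """Discount factor at time t (years post-surgery): 1 within the first
    year, then (1+r)^−(y−1) during year y."""
    if t_years < 0:
        raise ValueError("t_years must be >= 0")
    if t_years <= 1.0 or rate == 0.0:
        return 1.0
    return (1.0 + rate) ** (-(math.ceil(t_years) - 1))


def cycle_discount(cycle_index: int, rate: float) -> float:
    """Discount factor for Markov cycle k (cycle 0 = first post-entry year)."""
    return (1.0 + rate) ** (-cycle_index)


# ---------------------------------------------------------------------------
# acute-event disutility rules

REL, ABS = "relative-fraction", "absolute-decrement"

#: event day per kind: PE events at day 21, everything else at day 7
PE_KINDS = frozenset({"nonfatal_pe", "fatal_pe"})
FATAL_KINDS = frozenset({"fatal_pe", "fatal_mb", "hit_death"})


def event_day(kind: str) -> float:
    return 21.0 if kind in PE_KINDS else 7.0


def default_disutility_rules(u: UtilitySet) -> dict[str, list[tuple[str, float]]]:
    """Disutility rules per acute event kind, as (mode, value) lists.

    The 50:50 anticoagulant mix for treated VTE contributes half the
    warfarin-monitoring decrement to symptomatic proximal DVT and PE.
    """
    warf = u.warfarin_treated_abs * 0.5
    return {
        "sympt_prox_dvt": [(REL, u.sympt_prox_dvt_rel), (ABS, warf)],
        "sympt_dist_dvt": [(REL, u.sympt_dist_dvt_rel)],
        "nonfatal_pe": [(REL, u.nonfatal_pe_rel), (ABS, warf)],
        "fatal_pe": [],
        "ssb_return_to_theatre": [(REL, u.mb_rel)],
        "gi_bleed_intervention": [(REL, u.mb_rel)],
        "gi_bleed_medical": [(REL, u.mb_rel)],
        "other_mb": [(REL, u.mb_rel)],
        "ich_stroke": [(REL, u.ich_stroke_rel)],
        "fatal_mb": [],
        "crnmb_medical": [(ABS, u.crnmb_abs)],
        "wound_haematoma": [(ABS, u.crnmb_abs)],
        "ssi_medical": [(ABS, u.crnmb_abs), (REL, u.ssi_rel)],
        "ssi_return_to_theatre": [(ABS, u.crnmb_abs), (REL, u.ssi_rel)],
        "ssi_revision": [(ABS, u.crnmb_abs), (REL, u.ssi_rel)],
        "hit_success": [(ABS, u.hit_abs)],
        "hit_thrombosis": [(ABS, u.hit_abs), (REL, u.hit_thrombosis_rel)],
        "hit_mb": [(ABS, u.hit_abs), (REL, u.hit_mb_rel)],
        "hit_amputation": [(ABS, u.hit_abs), (ABS, u.post_amputation_abs)],
        "hit_death": [],
        "asympt_prox_dvt": [],
        "asympt_dist_dvt": [],
        "none": [],
    }


def _modified_value(base: float, rules: list[tuple[str, float]]) -> float:
    v = base
    for mode, value in rules:
        if mode == REL:
            v *= 1.0 - value
        elif mode == ABS:
            v -= value
        else:
            raise ValueError(f"unknown disutility mode {mode!r}")
    return max(v, EQ5D_FLOOR)


def event_qaly_loss(
    kind: str,
    rules: Mapping[str, list[tuple[str, float]]],
    trajectory: UtilityTrajectory,
) -> float:
    """Expected QALY loss (relative to the clean trajectory) for one event,
    applied from its event day to day 90.

    Fatal events truncate accrual at the event day; non-fatal events replace
    the trajectory by its rule-modified (and floored) value over the window.
    """
    if kind not in rules:
        raise KeyError(f"no disutility rule for event kind {kind!r}")
    day = event_day(kind)
    if kind in FATAL_KINDS:
        return trajectory.integral(day, ACUTE_WINDOW_DAYS) / DAYS_PER_YEAR
    kind_rules = rules[kind]
    if not kind_rules:
        return 0.0
    # trajectory is linear on [day, 90] (the anchor kink is at day 270), and
    # so is the modified value unless the floor binds; trapezoid is exact
    u0, u1 = trajectory.value(day), trajectory.value(ACUTE_WINDOW_DAYS)
    m0, m1 = _modified_value(u0, kind_rules), _modified_value(u1, kind_rules)
    if m0 > EQ5D_FLOOR and m1 > EQ5D_FLOOR:
        return ((u0 - m0) + (u1 - m1)) / 2.0 * (ACUTE_WINDOW_DAYS - day) / DAYS_PER_YEAR
    # floor binds somewhere: integrate on a fine grid
    total = 0.0
    steps = 256
    h = (ACUTE_WINDOW_DAYS - day) / steps
    for i in range(steps):
        t = day + (i + 0.5) * h
        u = trajectory.value(t)
        total += (u - _modified_value(u, kind_rules)) * h
    return total / DAYS_PER_YEAR


def acute_qalys(
    branch_table: Mapping[str, float],
    rules: Mapping[str, list[tuple[str, float]]],
    trajectory: UtilityTrajectory,
) -> float:
    """Expected discounted QALYs over days 0–90 (no discounting applies
    within the first year)."""
    base = trajectory.integral(0.0, ACUTE_WINDOW_DAYS) / DAYS_PER_YEAR
    loss = sum(
        p * event_qaly_loss(kind, rules, trajectory)
        for kind, p in branch_table.items()
        if p > 0.0
    )
    return base - loss


# ---------------------------------------------------------------------------
# acute event costs

#: treated symptomatic VTE kinds (acute treatment bundles apply)
TREATED_VTE_KINDS = frozenset({"sympt_prox_dvt", "nonfatal_pe"})


def acute_treatment_assignment(vte_kind: str, inputs: ModelInputs) -> float:
    """Expected treatment-bundle cost for an acute VTE event.

    Symptomatic proximal DVT and non-fatal PE are treated (the fixture costs
    already embed the 50:50 DOAC vs LMWH+warfarin mix, assumed 100%
    effective with no recurrence); symptomatic distal DVT carries its
    diagnosis/management cost; asymptomatic DVT is not diagnosed and costs
    nothing.
    """
    ev = inputs.costs.event
    if vte_kind == "sympt_prox_dvt":
        return ev["sympt_prox_dvt"]
    if vte_kind == "nonfatal_pe":
        return ev["nonfatal_pe"]
    if vte_kind == "sympt_dist_dvt":
        return ev["sympt_dist_dvt"]
    if vte_kind in ("asympt_prox_dvt", "asympt_dist_dvt"):
        return 0.0
    raise KeyError(f"not a VTE event kind: {vte_kind!r}")


def acute_event_costs(inputs: ModelInputs) -> dict[str, float]:
    """Unit cost per acute event kind (GBP).

    Other-site major bleeding is costed as medically-managed bleeding (the
    GI-without-intervention tariff; no dedicated figure is tabulated).
    """
    ev = inputs.costs.event
    hit_treat = ev["hit"]
    return {
        "sympt_prox_dvt": ev["sympt_prox_dvt"],
        "sympt_dist_dvt": ev["sympt_dist_dvt"],
        "nonfatal_pe": ev["nonfatal_pe"],
        "fatal_pe": 0.0,
        "ssb_return_to_theatre": ev["ssb_return_theatre"],
        "gi_bleed_intervention": ev["gi_with_intervention"],
        "gi_bleed_medical": ev["gi_without_intervention"],
        "ich_stroke": ev["stroke_admission"] + ev["stroke_acute_90d"],
        "other_mb": ev["gi_without_intervention"],
        "fatal_mb": 0.0,
        "crnmb_medical": ev["crnmb"],
        "wound_haematoma": ev["crnmb"],
        "ssi_medical": ev["crnmb"] + ev["ssi_medical"],
        "ssi_return_to_theatre": ev["crnmb"] + ev["ssb_return_theatre"],
        "ssi_revision": ev["crnmb"] + ev["revision_infected"],
        "hit_success": hit_treat,
        "hit_thrombosis": hit_treat + 0.5 * (ev["sympt_prox_dvt"] + ev["nonfatal_pe"]),
        "hit_mb": hit_treat + ev["gi_without_intervention"],
        "hit_death": hit_treat,
        "hit_amputation": hit_treat + ev["amputation_acute"],
        "asympt_prox_dvt": 0.0,
        "asympt_dist_dvt": 0.0,
        "none": 0.0,
    }


#: cost-breakdown category per acute event kind (report columns)
ACUTE_COST_CATEGORY = {
    "sympt_prox_dvt": "vte", "sympt_dist_dvt": "vte", "nonfatal_pe": "vte",
    "fatal_pe": "vte", "hit_thrombosis": "vte",
    "ssb_return_to_theatre": "bleeding", "gi_bleed_intervention": "bleeding",
    "gi_bleed_medical": "bleeding", "ich_stroke": "bleeding",
    "other_mb": "bleeding", "fatal_mb": "bleeding", "crnmb_medical": "bleeding",
    "wound_haematoma": "bleeding", "ssi_medical": "bleeding",
    "ssi_return_to_theatre": "bleeding", "ssi_revision": "bleeding",
    "hit_success": "bleeding", "hit_mb": "bleeding", "hit_death": "bleeding",
    "hit_amputation": "post_amputation",
    "asympt_prox_dvt": "vte", "asympt_dist_dvt": "vte", "none": "vte",
}


# ---------------------------------------------------------------------------
# Markov state values

STROKE_STATE = "disabled_post_stroke"


def markov_baseline_utility(cycle_index: int, inputs: ModelInputs) -> float:
    """Baseline utility during Markov cycle k (time-dependent).

    Cycle 0 averages the recovery trajectory over days 90–455; later cycles
    use the 9-month value less any configured annual decrement.
    """
    traj = trajectory_from(inputs.utilities)
    if cycle_index == 0:
        return traj.integral(90.0, 90.0 + DAYS_PER_YEAR) / DAYS_PER_YEAR
    value = inputs.utilities.post_9mo - (
        inputs.markov_config.annual_utility_decrement * cycle_index
    )
    return max(value, EQ5D_FLOOR)


def state_value(state: str, cycle_index: int, inputs: ModelInputs) -> tuple[float, float]:
    """(annual utility, annual cost) for one Markov state during cycle k.

    For entry-only states (post-stroke, post-amputation) cycle 0 is "year 1"
    of the state; PTS and CTEPH year-1 values live on their tunnel states.
    """
    u = inputs.utilities
    st = inputs.costs.state
    mc = inputs.markov_config
    base = markov_baseline_utility(cycle_index, inputs)
    first_year = cycle_index == 0

    if state == "dead":
        return 0.0, 0.0
    if state in ("well", "post_sympt_prox_dvt", "post_sympt_dist_dvt",
                 "post_asympt_prox_dvt", "post_asympt_dist_dvt", "post_pe"):
        return base, 0.0
    if state == "pts_mildmod_y1":
        return max(base - u.pts_mildmod_abs, EQ5D_FLOOR), st["pts_mildmod_y1"]
    if state == "pts_severe_y1":
        return max(base - u.pts_severe_abs, EQ5D_FLOOR), st["pts_severe_y1"]
    if state == "pts_mildmod_chronic":
        return max(base - u.pts_mildmod_abs, EQ5D_FLOOR), st["pts_mildmod_y2"]
    if state == "pts_severe_chronic":
        return max(base - u.pts_severe_abs, EQ5D_FLOOR), st["pts_severe_y2"]
    if state == "cteph_y1":
        cost = (mc.cteph_frac_operable * st["cteph_operable_y1"]
                + mc.cteph_frac_inoperable * st["cteph_inoperable_y1"]
                + mc.cteph_frac_recurrent * st["cteph_recurrent_y1"])
        return base * (1.0 - u.cteph_y1_rel), cost
    if state in ("cteph_recurrent_y2", "cteph_chronic"):
        # year-2+ utility: the post-treatment improvement applied to year 1
        util = base * (1.0 - u.cteph_y1_rel) * (1.0 + u.cteph_y2_improvement_rel)
        cost = st["cteph_recurrent_y2"] if state == "cteph_recurrent_y2" else st["cteph_chronic_y2"]
        return min(util, base), cost
    if state == "cteph_treated":
        return base, st["cteph_treated"]
    if state == STROKE_STATE:
        d = mc.stroke_dependent_frac
        if first_year:
            cost = d * st["stroke_y1_dependent"] + (1 - d) * st["stroke_y1_independent"]
        else:
            cost = d * st["stroke_y2_dependent"] + (1 - d) * st["stroke_y2_independent"]
        return base * (1.0 - u.post_stroke_rel), cost
    if state == "amputated_post_hit":
        cost = st["amputation_y1"] if first_year else st["amputation_y2"]
        return max(base - u.post_amputation_abs, EQ5D_FLOOR), cost
    if state == "post_revision_infection":
        return base * (1.0 - u.post_infected_revision_rel), 0.0
    raise KeyError(f"unknown Markov state {state!r}")


#: cost-breakdown category per Markov state
STATE_COST_CATEGORY = {
    "pts_mildmod_y1": "pts", "pts_severe_y1": "pts",
    "pts_mildmod_chronic": "pts", "pts_severe_chronic": "pts",
    "cteph_y1": "cteph", "cteph_recurrent_y2": "cteph",
    "cteph_chronic": "cteph", "cteph_treated": "cteph",
    STROKE_STATE: "bleeding", "amputated_post_hit": "post_amputation",
    "post_revision_infection": "bleeding",
}


def total_outcomes(acute, trace) -> tuple[float, float]:
    """Total discounted (QALYs, costs) for one strategy: acute + Markov."""
    return (acute.acute_qalys + trace.total_discounted_qalys,
            acute.acute_cost + trace.total_discounted_cost)


def cost_breakdown(acute, trace, inputs: ModelInputs) -> dict[str, float]:
    """Per-category discounted costs (prophylaxis, vte, bleeding, cteph,
    pts, post_amputation); categories sum to the total cost."""
    from .params import strategy_total_cost

    out = {"prophylaxis": strategy_total_cost(acute.strategy, inputs.costs),
           "vte": 0.0, "bleeding": 0.0, "cteph": 0.0, "pts": 0.0,
           "post_amputation": 0.0}
    unit = acute_event_costs(inputs)
    for kind, p in acute.branch_table.items():
        if p <= 0.0 or unit[kind] == 0.0:
            continue
        out[ACUTE_COST_CATEGORY[kind]] += p * unit[kind]
    for state, cost in trace.discounted_cost_by_state.items():
        if cost:
            out[STATE_COST_CATEGORY[state]] += cost
    return out
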