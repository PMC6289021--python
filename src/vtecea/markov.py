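"""Lifetime annual-cycle Markov cohort model from day 90 post-surgery.

Individuals enter in the state matching their acute-phase outcome and face
age-indexed background mortality in every state.  During the first two
cycles those in a post-VTE state can develop post-thrombotic syndrome (PTS),
and those post-PE can additionally develop chronic thromboembolic pulmonary
hypertension (CTEPH); both first years are tunnel states (one cycle of
residency).  CTEPH carries a one-time 20% mortality during its first year,
applied multiplicatively with background mortality.  Death is absorbing.

Two-year onset incidences are converted to per-cycle probabilities through
the usual rate↔probability transforms.  For the post-PE state, where PTS and
CTEPH compete, the combined two-year probability is converted and then split
proportionally to the marginal incidences so that the two-cycle composition
of EACH pathway reproduces its stated two-year incidence exactly (a naive
independent conversion under competition cannot).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import ModelInputs
from .valuation import cycle_discount, state_value

STATES = (
    "well",
    "post_sympt_prox_dvt",
    "post_sympt_dist_dvt",
    "post_asympt_prox_dvt",
    "post_asympt_dist_dvt",
    "post_pe",
    "pts_mildmod_y1",
    "pts_severe_y1",
    "pts_mildmod_chronic",
    "pts_severe_chronic",
    "cteph_y1",
    "cteph_recurrent_y2",
    "cteph_chronic",
    "cteph_treated",
    "disabled_post_stroke",
    "amputated_post_hit",
    "post_revision_infection",
    "dead",
)
S = {name: i for i, name in enumerate(STATES)}
N_STATES = len(STATES)

TUNNEL_STATES = ("pts_mildmod_y1", "pts_severe_y1", "cteph_y1", "cteph_recurrent_y2")

#: post-VTE states and their 2-year PTS incidence parameter
_PTS_ANTECEDENTS = {
    "post_sympt_prox_dvt": "pts_2yr_sympt_prox_dvt",
    "post_sympt_dist_dvt": "pts_2yr_sympt_dist_dvt",
    "post_asympt_prox_dvt": "pts_2yr_asympt_prox_dvt",
    "post_asympt_dist_dvt": "pts_2yr_asympt_dist_dvt",
}

ONSET_CYCLES = 2  # PTS/CTEPH onset restricted to the first two Markov cycles


def rate_from_probability(p: float, t: float) -> float:
    """Constant event rate r such that P(event within t years) = p."""
    if not (0.0 <= p < 1.0):
        raise ValueError(f"probability must lie in [0, 1), got {p}")
    if t <= 0:
        raise ValueError("t must be > 0")
    return -math.log(1.0 - p) / t

def probability_from_rate(r: float, t: float) -> float:
    """P(event within t years) under constant rate r; inverse of
    :func:`rate_from_probability` for matching t."""
    if r < 0:
        raise ValueError("rate must be >= 0")
    if t <= 0:
        raise ValueError("t must be > 0")
    return 1.0 - math.exp(-r * t)


def _per_cycle_onset(p_2yr: float, cycle_length: float = 1.0) -> float:
    """Per-cycle onset probability composing to the 2-year incidence."""
    return probability_from_rate(rate_from_probability(p_2yr, 2.0), cycle_length)


def build_transition_matrix(
    inputs: ModelInputs, cycle_index: int, current_age: float
) -> np.ndarray:
    """One-cycle transition matrix (rows sum to 1)."""
    lt = inputs.long_term
    q = inputs.life_table.lookup(current_age)
    surv = 1.0 - q
    sev = lt.prop_pts_severe
    cyc = inputs.settings.cycle_length_years

    m = np.zeros((N_STATES, N_STATES))
    m[:, S["dead"]] = q
    m[S["dead"], :] = 0.0
    m[S["dead"], S["dead"]] = 1.0

    onset_window = cycle_index < ONSET_CYCLES

    # default: stay put (survivors)
    for state in STATES[:-1]:
        m[S[state], S[state]] = surv

    if onset_window:
        for state, param in _PTS_ANTECEDENTS.items():
            p = _per_cycle_onset(getattr(lt, param), cyc)
            i = S[state]
            m[i, S["pts_severe_y1"]] = surv * p * sev
            m[i, S["pts_mildmod_y1"]] = surv * p * (1.0 - sev)
            m[i, i] = surv * (1.0 - p)
        # post-PE: PTS and CTEPH compete; joint conversion preserves both
        # marginal 2-year incidences under two-cycle composition
        p_pts2, p_ct2 = lt.pts_2yr_nonfatal_pe, lt.cteph_2yr_after_pe
        total2 = p_pts2 + p_ct2
        i = S["post_pe"]
        if total2 > 0:
            if total2 >= 1.0:
                raise ValueError("combined post-PE 2-year onset probability >= 1")
            p_tot = _per_cycle_onset(total2, cyc)
            p_ct = p_tot * p_ct2 / total2
            p_pts = p_tot * p_pts2 / total2
            m[i, S["cteph_y1"]] = surv * p_ct
            m[i, S["pts_severe_y1"]] = surv * p_pts * sev
            m[i, S["pts_mildmod_y1"]] = surv * p_pts * (1.0 - sev)
            m[i, i] = surv * (1.0 - p_tot)

    # tunnels: exactly one cycle of residency
    i = S["pts_mildmod_y1"]
    m[i, i] = 0.0
    m[i, S["pts_mildmod_chronic"]] = surv
    i = S["pts_severe_y1"]
    m[i, i] = 0.0
    m[i, S["pts_severe_chronic"]] = surv
    i = S["cteph_y1"]
    cm = lt.cteph_mortality
    alive = surv * (1.0 - cm)
    m[i, i] = 0.0
    m[i, S["dead"]] = 1.0 - alive
    m[i, S["cteph_recurrent_y2"]] = alive * inputs.markov_config.cteph_frac_recurrent
    m[i, S["cteph_treated"]] = alive * (1.0 - inputs.markov_config.cteph_frac_recurrent)
    i = S["cteph_recurrent_y2"]
    m[i, i] = 0.0
    m[i, S["cteph_chronic"]] = surv

    rowsums = m.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-12):
        raise ValueError(f"transition rows do not sum to 1: {rowsums}")
    if (m < -1e-15).any():
        raise ValueError("negative transition probability (over-specified competing risks)")
    return m


@dataclass
class MarkovTrace:
    """State occupancy by cycle with per-cycle (discounted) costs/QALYs."""

    occupancy: np.ndarray          # (n_cycles + 1, n_states), start-of-cycle
    cycle_ages: np.ndarray         # age at the start of each cycle
    cost: np.ndarray               # (n_cycles,) undiscounted
    qaly: np.ndarray
    cost_disc: np.ndarray
    qaly_disc: np.ndarray
    discounted_cost_by_state: dict

    @property
    def n_cycles(self) -> int:
        return len(self.cost)

    @property
    def total_discounted_cost(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_discounted_qalys(self) -> float:
        return float(self.qaly_disc.sum())

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy[:-1], columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.n_cycles))
        df.insert(1, "age", self.cycle_ages)
        df["cost"] = self.cost
        df["qaly"] = self.qaly
        df["cost_disc"] = self.cost_disc
        df["qaly_disc"] = self.qaly_disc
        return df


def entry_vector(entry: dict[str, float]) -> np.ndarray:
    v = np.zeros(N_STATES)
    for state, p in entry.items():
        try:
            v[S[state]] += p
        except KeyError as exc:
            raise KeyError(f"unknown entry state {state!r}") from exc
    return v


def run_cohort(entry: dict[str, float] | np.ndarray, inputs: ModelInputs) -> MarkovTrace:
    """Cohort simulation from model entry (day 90) to the horizon.

    ``entry`` may sum to less than 1; the remainder is assigned to the dead
    state (acute-phase deaths).  Annual cycles run until the configured
    horizon or the life-table terminal age.
    """
    occ0 = entry if isinstance(entry, np.ndarray) else entry_vector(entry)
    occ0 = occ0.astype(float).copy()
    total = occ0.sum()
    if total > 1.0 + 1e-9:
        raise ValueError(f"entry distribution sums to {total} > 1")
    occ0[S["dead"]] += max(0.0, 1.0 - total)

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

    occ = np.empty((max_cycles + 1, N_STATES))
    occ[0] = occ0
    ages = np.empty(max_cycles)
    cost = np.empty(max_cycles)
    qaly = np.empty(max_cycles)
    cost_disc = np.empty(max_cycles)
    qaly_disc = np.empty(max_cycles)
    cost_by_state = np.zeros(N_STATES)

    util_vec = np.empty(N_STATES)
    cost_vec = np.empty(N_STATES)
    n_run = 0
    for k in range(max_cycles):
        age = entry_age + k * inputs.settings.cycle_length_years
        m = build_transition_matrix(inputs, k, age)
        occ[k + 1] = occ[k] @ m
        basis = 0.5 * (occ[k] + occ[k + 1]) if half else occ[k]
        for i, state in enumerate(STATES):
            util_vec[i], cost_vec[i] = state_value(state, k, inputs)
        d = cycle_discount(k, rate)
        ages[k] = age
        cost[k] = float(basis @ cost_vec)
        qaly[k] = float(basis @ util_vec)
        cost_disc[k] = cost[k] * d
        qaly_disc[k] = qaly[k] * d
        cost_by_state += d * basis * cost_vec
        n_run = k + 1
        if occ[k + 1][S["dead"]] > 1.0 - 1e-12:
            break

    sl = slice(0, n_run)
    return MarkovTrace(
        occupancy=occ[: n_run + 1],
        cycle_ages=ages[sl],
        cost=cost[sl],
        qaly=qaly[sl],
        cost_disc=cost_disc[sl],
        qaly_disc=qaly_disc[sl],
        discounted_cost_by_state={
            state: float(cost_by_state[i]) for i, state in enumerate(STATES)
            if cost_by_state[i] != 0.0
        },
    )
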