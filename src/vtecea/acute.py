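"""The 90-day acute-phase decision tree.

Per strategy, four independent hazard "arms" are combined: the VTE outcome
(no event / asymptomatic distal / asymptomatic proximal / symptomatic distal
/ symptomatic proximal DVT / non-fatal PE / fatal PE), the major-bleeding
outcome (surgical-site bleed returning to theatre, GI bleed with or without
intervention, intracranial haemorrhage causing permanent disability, other
major bleeding, fatal bleeding), the clinically-relevant non-major bleeding
chain (medical management, or wound haematoma possibly progressing to a
surgical-site infection managed medically or surgically, the surgical cases
splitting 1:1 between return to theatre and revision arthroplasty), and the
heparin-induced thrombocytopenia chain (success / new thrombosis / major
bleed / death, plus an amputation fraction).

Only one symptomatic event is allowed in the first 90 days.  Joint
occurrences are resolved by a strict global priority ranking — fatal events,
then PE, then symptomatic DVT, then major bleeding, then CRNMB — and the
suppressed event's mass is reassigned to the surviving (primary) event.
With independent arms this resolution has a closed form: the probability
that outcome o is primary is its own probability times, for every other arm,
the probability that that arm produced a strictly lower-priority outcome.
Asymptomatic DVT is not a symptomatic event: it is never suppressed (its
expected counts stay marginal) but it only determines the Markov entry state
when no lasting symptomatic outcome occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from .params import strategy_total_cost
from .types import ModelInputs
from .valuation import (
    acute_event_costs,
    acute_qalys,
    default_disutility_rules,
    trajectory_from,
)

#: global priority ranking (1 = highest) implementing the single-symptomatic-
#: event rule; class-0 outcomes (asymptomatic DVT, HIT treated successfully
#: without sequelae is ranked lowest among events, "none") never suppress.
RANK = {
    "fatal_pe": 1,
    "fatal_mb": 2,
    "hit_death": 3,
    "nonfatal_pe": 4,
    "sympt_prox_dvt": 5,
    "sympt_dist_dvt": 6,
    "hit_thrombosis": 7,
    "ich_stroke": 8,
    "ssb_return_to_theatre": 9,
    "gi_bleed_intervention": 10,
    "gi_bleed_medical": 11,
    "other_mb": 12,
    "hit_mb": 13,
    "hit_amputation": 14,
    "ssi_revision": 15,
    "ssi_return_to_theatre": 16,
    "ssi_medical": 17,
    "wound_haematoma": 18,
    "crnmb_medical": 19,
    "hit_success": 20,
}

#: Markov entry state per event kind; "hit_thrombosis" splits 1:1 between
#: proximal DVT and PE downstream.
ENTRY_STATE = {
    "fatal_pe": "dead", "fatal_mb": "dead", "hit_death": "dead",
    "nonfatal_pe": "post_pe",
    "sympt_prox_dvt": "post_sympt_prox_dvt",
    "sympt_dist_dvt": "post_sympt_dist_dvt",
    "ich_stroke": "disabled_post_stroke",
    "hit_amputation": "amputated_post_hit",
    "ssi_revision": "post_revision_infection",
    "ssb_return_to_theatre": "well", "gi_bleed_intervention": "well",
    "gi_bleed_medical": "well", "other_mb": "well", "hit_mb": "well",
    "ssi_return_to_theatre": "well", "ssi_medical": "well",
    "wound_haematoma": "well", "crnmb_medical": "well", "hit_success": "well",
    "asympt_prox_dvt": "post_asympt_prox_dvt",
    "asympt_dist_dvt": "post_asympt_dist_dvt",
    "none": "well",
}

_CLASS0 = ("asympt_prox_dvt", "asympt_dist_dvt", "none")


def _check_prob(p: float, label: str) -> None:
    if not (-1e-12 <= p <= 1.0 + 1e-12):
        raise ValueError(f"{label} outside [0, 1]: {p}")


@dataclass
class AcuteTree:
    """Evaluated tree for one strategy.

    ``branches`` partitions the cohort by primary event kind (plus the
    asymptomatic/no-event residual) and sums to 1; ``marginals`` holds the
    per-arm unsuppressed outcome probabilities used for event tallies.
    """

    strategy: str
    branches: dict[str, float]
    marginals: dict[str, dict[str, float]]
    q3_well: float  # P(bleed/CRNMB/HIT arms produce nothing state-changing)

    def items(self):
        return self.branches.items()

    def __getitem__(self, kind: str) -> float:
        return self.branches[kind]


@dataclass
class AcuteResult:
    strategy: str
    branch_table: dict[str, float]
    tallies_per_1000: dict[str, float]
    acute_cost: float
    acute_qalys: float
    entry_distribution: dict[str, float]
    deaths_90d: float
    rounded_tallies: dict[str, int] = field(default_factory=dict)


def _vte_arm(inputs: ModelInputs, strategy: str) -> dict[str, float]:
    b = inputs.baseline
    cfg = inputs.tree_config
    if strategy == inputs.comparator:
        dvt_total, pe = b.total_dvt, b.nonfatal_pe
    else:
        r = inputs.absolute_risks[strategy]
        dvt_total, pe = r.dvt.value, r.pe.value
    sympt_frac = b.symptomatic_dvt / b.total_dvt if b.total_dvt > 0 else 0.0
    sympt = dvt_total * sympt_frac
    asympt = dvt_total - sympt
    f = b.pe_case_fatality
    if cfg.pe_fatality_mode == "of_nonfatal":
        nonfatal, fatal = pe, pe * f / (1.0 - f)
    else:  # printed risk covers all PE
        nonfatal, fatal = pe * (1.0 - f), pe * f
    arm = {
        "sympt_prox_dvt": sympt * b.prop_symptomatic_proximal,
        "sympt_dist_dvt": sympt * (1.0 - b.prop_symptomatic_proximal),
        "asympt_prox_dvt": asympt * b.prop_asymptomatic_proximal,
        "asympt_dist_dvt": asympt * (1.0 - b.prop_asymptomatic_proximal),
        "nonfatal_pe": nonfatal,
        "fatal_pe": fatal,
    }
    arm["none"] = 1.0 - sum(arm.values())
    return arm


def _bleed_arm(inputs: ModelInputs, strategy: str) -> dict[str, float]:
    b = inputs.baseline
    cfg = inputs.tree_config
    if strategy == inputs.comparator:
        ssb, gi_ich, other = b.mb_surgical_site, b.mb_gi_ich, b.mb_other
    else:
        r = inputs.absolute_risks[strategy]
        ssb, gi_ich, other = r.ssb.value, r.gi_ich.value, r.other_mb.value
    gi = gi_ich * cfg.gi_share_of_gi_ich
    ich = gi_ich - gi
    arm = {
        "ssb_return_to_theatre": ssb * cfg.return_to_theatre_after_ssb,
        "gi_bleed_intervention": gi * cfg.gi_intervention_frac,
        "gi_bleed_medical": gi * (1.0 - cfg.gi_intervention_frac),
        "ich_stroke": ich,
        "other_mb": other,
        "fatal_mb": cfg.fatal_mb_prob,
    }
    arm["none"] = 1.0 - sum(arm.values())
    return arm


def _crnmb_arm(inputs: ModelInputs, strategy: str) -> dict[str, float]:
    b = inputs.baseline
    cfg = inputs.tree_config
    if strategy == inputs.comparator:
        c = b.crnmb
    else:
        c = inputs.absolute_risks[strategy].crnmb.value
    haem = c * b.wound_haematoma_frac_of_crnmb
    ssi = haem * cfg.ssi_given_haematoma
    surgical = ssi * cfg.surgical_mgmt_given_ssi
    arm = {
        "crnmb_medical": c - haem,
        "wound_haematoma": haem - ssi,
        "ssi_medical": ssi - surgical,
        "ssi_revision": surgical * cfg.revision_vs_return_ratio,
        "ssi_return_to_theatre": surgical * (1.0 - cfg.revision_vs_return_ratio),
    }
    arm["none"] = 1.0 - sum(arm.values())
    return arm


def _hit_arm(inputs: ModelInputs, strategy: str) -> dict[str, float]:
    h = inputs.baseline.hit
    cfg = inputs.tree_config
    arm = {
        "hit_success": h * (cfg.hit_frac_success - cfg.hit_amputation_prob),
        "hit_amputation": h * cfg.hit_amputation_prob,
        "hit_thrombosis": h * cfg.hit_frac_thrombosis,
        "hit_mb": h * cfg.hit_frac_mb,
        "hit_death": h * cfg.hit_frac_death,
    }
    arm["none"] = 1.0 - sum(arm.values())
    return arm


def build_acute_tree(inputs: ModelInputs, strategy: str) -> AcuteTree:
    """Evaluate the decision tree: mutually exclusive terminal branches."""
    if strategy not in inputs.strategy_names:
        raise KeyError(f"unknown strategy {strategy!r}")
    arms = {
        "vte": _vte_arm(inputs, strategy),
        "bleed": _bleed_arm(inputs, strategy),
        "crnmb": _crnmb_arm(inputs, strategy),
        "hit": _hit_arm(inputs, strategy),
    }
    for arm_name, arm in arms.items():
        for kind, p in arm.items():
            _check_prob(p, f"{strategy}/{arm_name}/{kind}")

    def lower_mass(arm: dict[str, float], rank: int) -> float:
        """Mass of outcomes in an arm with strictly lower priority."""
        return sum(p for k, p in arm.items() if RANK.get(k, 10**9) > rank)

    branches: dict[str, float] = {}
    for arm_name, arm in arms.items():
        for kind, p in arm.items():
            if kind in RANK and p > 0.0:
                resolved = p
                for other_name, other in arms.items():
                    if other_name != arm_name:
                        resolved *= lower_mass(other, RANK[kind])
                branches[kind] = resolved

    # residual: no symptomatic event anywhere
    class0_other = 1.0
    for arm_name in ("bleed", "crnmb", "hit"):
        class0_other *= sum(
            p for k, p in arms[arm_name].items() if k not in RANK
        )
    for kind in _CLASS0:
        branches[kind] = arms["vte"].get(kind, 0.0) * class0_other

    total = sum(branches.values())
    if abs(total - 1.0) > 1e-10:
        raise ValueError(
            f"branch probabilities for {strategy!r} sum to {total!r}, not 1"
        )

    # P(the bleed/CRNMB/HIT arms jointly produce no lasting-state outcome):
    # decomposition by the highest-priority outcome among those three arms,
    # keeping only well-mapped primaries and the all-quiet term.
    bch = {k: arms[k] for k in ("bleed", "crnmb", "hit")}
    q3 = 1.0
    for arm in bch.values():
        q3 *= sum(p for k, p in arm.items() if k not in RANK)
    for arm_name, arm in bch.items():
        for kind, p in arm.items():
            if kind in RANK and ENTRY_STATE.get(kind) == "well" and p > 0.0:
                term = p
                for other_name, other in bch.items():
                    if other_name != arm_name:
                        term *= lower_mass(other, RANK[kind])
                q3 += term

    return AcuteTree(strategy=strategy, branches=branches, marginals=arms, q3_well=q3)


def tally_events(tree: AcuteTree, cohort_size: float = 1000.0) -> dict[str, float]:
    """Expected event counts per ``cohort_size`` patients.

    Symptomatic events count once each under the single-event rule (resolved
    primaries); asymptomatic DVT — undiagnosed and never suppressed — counts
    marginally.  Aggregates follow the report conventions: ``sympt_dvt``,
    ``asympt_dvt``, ``total_vte`` (symptomatic + asymptomatic DVT +
    non-fatal PE) and acute ``deaths``.
    """
    t = {k: p * cohort_size for k, p in tree.branches.items() if k in RANK}
    t["asympt_prox_dvt"] = tree.marginals["vte"]["asympt_prox_dvt"] * cohort_size
    t["asympt_dist_dvt"] = tree.marginals["vte"]["asympt_dist_dvt"] * cohort_size
    t["sympt_dvt"] = t.get("sympt_prox_dvt", 0.0) + t.get("sympt_dist_dvt", 0.0)
    t["asympt_dvt"] = t["asympt_prox_dvt"] + t["asympt_dist_dvt"]
    t["total_vte"] = t["sympt_dvt"] + t["asympt_dvt"] + t.get("nonfatal_pe", 0.0)
    t["deaths"] = (t.get("fatal_pe", 0.0) + t.get("fatal_mb", 0.0)
                   + t.get("hit_death", 0.0))
    return t


def round_half_even(x: float) -> int:
    """Nearest integer, ties to even (the report rounding convention)."""
    return int(round(x))


def entry_distribution(tree: AcuteTree) -> dict[str, float]:
    """Distribution over Markov entry states (dead included; sums to 1)."""
    entry: dict[str, float] = {}
    for kind, p in tree.branches.items():
        if p <= 0.0:
            continue
        if kind in _CLASS0:
            continue  # handled via the residual below
        if kind == "hit_thrombosis":
            entry["post_sympt_prox_dvt"] = entry.get("post_sympt_prox_dvt", 0.0) + 0.5 * p
            entry["post_pe"] = entry.get("post_pe", 0.0) + 0.5 * p
            continue
        state = ENTRY_STATE.get(kind)
        if state is None:
            raise KeyError(f"no entry-state mapping for branch {kind!r}")
        if state != "well":
            entry[state] = entry.get(state, 0.0) + p
    # residual: no lasting-state outcome from bleeding/CRNMB/HIT (q3_well
    # covers both "nothing happened" and well-mapped symptomatic primaries);
    # the VTE arm's class-0 outcome then decides between well and the
    # asymptomatic post states
    vte = tree.marginals["vte"]
    entry["well"] = entry.get("well", 0.0) + vte["none"] * tree.q3_well
    entry["post_asympt_prox_dvt"] = (entry.get("post_asympt_prox_dvt", 0.0)
                                     + vte["asympt_prox_dvt"] * tree.q3_well)
    entry["post_asympt_dist_dvt"] = (entry.get("post_asympt_dist_dvt", 0.0)
                                     + vte["asympt_dist_dvt"] * tree.q3_well)
    total = sum(entry.values())
    if abs(total - 1.0) > 1e-10:
        raise ValueError(f"entry distribution sums to {total!r}, not 1")
    return entry


def evaluate_acute(inputs: ModelInputs, strategy: str) -> AcuteResult:
    """Run the tree and value it: tallies, entry states, costs and QALYs."""
    tree = build_acute_tree(inputs, strategy)
    tallies = tally_events(tree)
    entry = entry_distribution(tree)
    unit_costs = acute_event_costs(inputs)
    cost = strategy_total_cost(strategy, inputs.costs)
    for kind, p in tree.branches.items():
        if p > 0.0:
            cost += p * unit_costs[kind]
    rules = default_disutility_rules(inputs.utilities)
    qalys = acute_qalys(tree.branches, rules, trajectory_from(inputs.utilities))
    deaths = entry.get("dead", 0.0)
    rounded = {k: round_half_even(v) for k, v in tallies.items()}
    return AcuteResult(
        strategy=strategy,
        branch_table=tree.branches,
        tallies_per_1000=tallies,
        acute_cost=cost,
        acute_qalys=qalys,
        entry_distribution=entry,
        deaths_90d=deaths,
        rounded_tallies=rounded,
    )
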