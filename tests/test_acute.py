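"""Acute-phase decision tree: conservation, oracles, tallies, entry states."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from vtecea.acute import (
    ENTRY_STATE,
    RANK,
    build_acute_tree,
    entry_distribution,
    evaluate_acute,
    tally_events,
)
from vtecea.valuation import acute_treatment_assignment


def brute_force_resolution(arms):
    """Exhaustive enumeration oracle: joint outcomes over the four
    independent arms, the single-symptomatic-event rule applied by picking
    the highest-priority (lowest-rank) outcome per combination."""
    branch = {}
    entry = {}
    arm_items = [list(a.items()) for a in arms.values()]
    for combo in itertools.product(*arm_items):
        p = 1.0
        for _, prob in combo:
            p *= prob
        if p == 0.0:
            continue
        kinds = [k for k, _ in combo]
        ranked = [k for k in kinds if k in RANK]
        if ranked:
            primary = min(ranked, key=RANK.__getitem__)
        else:
            vte_kind = kinds[0]  # the VTE arm's class-0 outcome decides
            primary = vte_kind
        branch[primary] = branch.get(primary, 0.0) + p
        # entry state: lasting state of the primary, else asymptomatic/well
        if primary == "hit_thrombosis":
            entry["post_sympt_prox_dvt"] = entry.get("post_sympt_prox_dvt", 0.0) + 0.5 * p
            entry["post_pe"] = entry.get("post_pe", 0.0) + 0.5 * p
            continue
        state = ENTRY_STATE[primary]
        if state == "well":
            state = ENTRY_STATE[kinds[0]]  # asymptomatic DVT persists
        entry[state] = entry.get(state, 0.0) + p
    return branch, entry


def test_closed_form_matches_enumeration_oracle(any_inputs):
    """The suppression algebra equals brute-force joint enumeration for
    every strategy (branch probabilities and entry states, 1e-12)."""
    for strategy in any_inputs.strategy_names:
        tree = build_acute_tree(any_inputs, strategy)
        branch, entry = brute_force_resolution(tree.marginals)
        for kind in set(branch) | set(tree.branches):
            assert tree.branches.get(kind, 0.0) == pytest.approx(
                branch.get(kind, 0.0), abs=1e-12), (strategy, kind)
        got = entry_distribution(tree)
        for state in set(entry) | set(got):
            assert got.get(state, 0.0) == pytest.approx(
                entry.get(state, 0.0), abs=1e-12), (strategy, state)


def test_three_event_toy_matches_enumeration():
    """Tiny hand-specified toy: enumeration and closed form agree exactly."""
    from vtecea.synthetic import make_inputs

    inputs = make_inputs()
    b = replace(
        inputs.baseline, total_dvt=0.2, symptomatic_dvt=0.1, nonfatal_pe=0.05,
        mb_surgical_site=0.1, mb_gi_ich=0.0, mb_other=0.0, crnmb=0.3, hit=0.0,
    )
    toy = inputs.replace(baseline=b)
    tree = build_acute_tree(toy, toy.comparator)
    branch, _ = brute_force_resolution(tree.marginals)
    for kind, p in branch.items():
        assert tree.branches[kind] == pytest.approx(p, abs=1e-12)


def test_branch_conservation_all_strategies(any_inputs):
    for strategy in any_inputs.strategy_names:
        tree = build_acute_tree(any_inputs, strategy)
        assert sum(tree.branches.values()) == pytest.approx(1.0, abs=1e-12)


def test_entry_distribution_conservation(any_inputs):
    for strategy in any_inputs.strategy_names:
        entry = entry_distribution(build_acute_tree(any_inputs, strategy))
        assert sum(entry.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= 0 for p in entry.values())


def test_zero_risk_inputs_single_no_event_branch(ethr_inputs):
    b = ethr_inputs.baseline
    zero = replace(
        b, total_dvt=0.0, symptomatic_dvt=0.0, nonfatal_pe=0.0,
        mb_surgical_site=0.0, mb_gi_ich=0.0, mb_other=0.0, crnmb=0.0, hit=0.0,
    )
    inputs = ethr_inputs.replace(baseline=zero)
    tree = build_acute_tree(inputs, inputs.comparator)
    live = {k: p for k, p in tree.branches.items() if p > 0}
    assert live == {"none": pytest.approx(1.0)}
    tallies = tally_events(tree)
    assert all(v == 0 for v in tallies.values())


def test_gi_intervention_split_is_13_percent(ethr_inputs):
    tree = build_acute_tree(ethr_inputs, ethr_inputs.comparator)
    gi_any = tree.branches["gi_bleed_intervention"] + tree.branches["gi_bleed_medical"]
    assert tree.branches["gi_bleed_intervention"] / gi_any == pytest.approx(0.13)


def test_ssi_surgical_cases_split_one_to_one(ethr_inputs):
    tree = build_acute_tree(ethr_inputs, ethr_inputs.comparator)
    assert tree.branches["ssi_revision"] == pytest.approx(
        tree.branches["ssi_return_to_theatre"], rel=1e-12)


def test_no_hit_mass_when_hit_risk_zero(ethr_inputs):
    inputs = ethr_inputs.replace(baseline=replace(ethr_inputs.baseline, hit=0.0))
    tree = build_acute_tree(inputs, inputs.comparator)
    for kind, p in tree.branches.items():
        if kind.startswith("hit_"):
            assert p == 0.0


def test_monotonicity_in_event_risk(ethr_inputs):
    """Raising one event risk weakly raises its tally and lowers 'none'."""
    base_tree = build_acute_tree(ethr_inputs, ethr_inputs.comparator)
    base_t = tally_events(base_tree)
    bumped = ethr_inputs.replace(
        baseline=replace(ethr_inputs.baseline, crnmb=ethr_inputs.baseline.crnmb * 2)
    )
    new_tree = build_acute_tree(bumped, bumped.comparator)
    new_t = tally_events(new_tree)
    assert new_t["crnmb_medical"] >= base_t["crnmb_medical"]
    assert new_tree.branches["none"] <= base_tree.branches["none"]


class TestEntryMapping:
    def test_fatal_and_lasting_branches_map_to_states(self, ethr_inputs):
        tree = build_acute_tree(ethr_inputs, ethr_inputs.comparator)
        entry = entry_distribution(tree)
        assert entry["dead"] == pytest.approx(
            tree.branches["fatal_pe"] + tree.branches.get("fatal_mb", 0.0)
            + tree.branches["hit_death"], abs=1e-15)
        assert entry["disabled_post_stroke"] == pytest.approx(
            tree.branches["ich_stroke"], abs=1e-15)
        assert entry["post_revision_infection"] == pytest.approx(
            tree.branches["ssi_revision"], abs=1e-15)

    def test_asymptomatic_events_reach_their_own_states(self, etkr_inputs):
        entry = entry_distribution(build_acute_tree(etkr_inputs, etkr_inputs.comparator))
        assert entry["post_asympt_prox_dvt"] > 0
        assert entry["post_asympt_dist_dvt"] > entry["post_asympt_prox_dvt"]


class TestTallies:
    def test_comparator_tallies_match_report_tables(self, ethr_inputs, etkr_inputs):
        hip = evaluate_acute(ethr_inputs, ethr_inputs.comparator).rounded_tallies
        assert hip["total_vte"] == 62
        assert hip["asympt_dvt"] == 46
        assert hip["nonfatal_pe"] == 7
        assert hip["sympt_prox_dvt"] == 8
        knee = evaluate_acute(etkr_inputs, etkr_inputs.comparator).rounded_tallies
        assert knee["total_vte"] == 144
        assert knee["asympt_dvt"] == 134
        assert knee["sympt_dvt"] == 6

    def test_asymptomatic_tallies_are_marginal(self, etkr_inputs):
        """Asymptomatic DVT is never suppressed by unrelated symptomatic
        events: its expected count equals risk x cohort size."""
        tree = build_acute_tree(etkr_inputs, etkr_inputs.comparator)
        t = tally_events(tree)
        assert t["asympt_dvt"] == pytest.approx(
            etkr_inputs.baseline.asymptomatic_dvt * 1000, abs=1e-9)


class TestTreatmentAssignment:
    def test_treated_and_untreated_kinds(self, ethr_inputs):
        assert acute_treatment_assignment("asympt_prox_dvt", ethr_inputs) == 0.0
        assert acute_treatment_assignment("sympt_prox_dvt", ethr_inputs) == 457
        assert acute_treatment_assignment("nonfatal_pe", ethr_inputs) == 991

    def test_non_vte_kind_rejected(self, ethr_inputs):
        with pytest.raises(KeyError):
            acute_treatment_assignment("ich_stroke", ethr_inputs)


def test_acute_result_costs_and_qalys_finite(any_inputs):
    for strategy in any_inputs.strategy_names:
        res = evaluate_acute(any_inputs, strategy)
        assert np.isfinite(res.acute_cost) and res.acute_cost >= 0
        assert 0 < res.acute_qalys <= 90.0 / 365.25
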