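"""Markov engine: conversions, transitions, tunnels, cohort accrual."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtecea.markov import (
    N_STATES,
    S,
    STATES,
    TUNNEL_STATES,
    build_transition_matrix,
    probability_from_rate,
    rate_from_probability,
    run_cohort,
)
from vtecea.pipeline import markov_components
from vtecea.synthetic import make_life_table
from vtecea.types import LifeTable


def zero_mortality_inputs(base):
    """Fixture inputs with a no-death life table (terminal age excepted)."""
    lt = make_life_table(a=0.0, b=0.0)
    return base.replace(life_table=lt)


class TestRateConversions:
    @pytest.mark.parametrize(
        "p,t,expected",
        [
            (0.0, 1.0, 0.0),
            (0.032, 2.0, -math.log(1 - 0.032) / 2),
            (0.40, 2.0, -math.log(0.6) / 2),
        ],
    )
    def test_rate_from_probability(self, p, t, expected):
        assert rate_from_probability(p, t) == pytest.approx(expected, abs=1e-15)

    def test_probability_from_rate_examples(self):
        assert probability_from_rate(0.0, 1.0) == 0.0
        assert probability_from_rate(0.0162624, 1.0) == pytest.approx(
            1 - math.exp(-0.0162624), abs=1e-12)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            rate_from_probability(1.0, 2.0)

    @settings(max_examples=200, deadline=None)
    @given(p=st.floats(min_value=0.0, max_value=0.999),
           t=st.floats(min_value=0.05, max_value=20.0))
    def test_round_trip(self, p, t):
        assert probability_from_rate(rate_from_probability(p, t), t) == pytest.approx(
            p, abs=1e-12)

    def test_two_year_recomposition(self):
        """2-year probability -> annual p -> 1-(1-p)^2 recovers the input."""
        p_annual = probability_from_rate(rate_from_probability(0.15, 2.0), 1.0)
        assert 1 - (1 - p_annual) ** 2 == pytest.approx(0.15, abs=1e-12)


class TestTransitionMatrix:
    def test_rows_sum_to_one_every_cycle(self, any_inputs):
        for k in (0, 1, 2, 10, 40):
            m = build_transition_matrix(any_inputs, k, 69.0 + k)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= -1e-15).all()

    def test_identity_when_no_morbidity_no_mortality(self, ethr_inputs):
        lt_zero = replace(
            ethr_inputs.long_term,
            pts_2yr_sympt_prox_dvt=0.0, pts_2yr_sympt_dist_dvt=0.0,
            pts_2yr_asympt_prox_dvt=0.0, pts_2yr_asympt_dist_dvt=0.0,
            pts_2yr_nonfatal_pe=0.0, cteph_2yr_after_pe=0.0, cteph_mortality=0.0,
        )
        inputs = zero_mortality_inputs(ethr_inputs.replace(long_term=lt_zero))
        m = build_transition_matrix(inputs, 0, 69.0)
        # tunnels still advance, everything else is the identity
        keep = [i for i, s in enumerate(STATES) if s not in TUNNEL_STATES]
        np.testing.assert_allclose(m[np.ix_(keep, keep)], np.eye(len(keep)), atol=1e-15)

    def test_well_row_is_background_mortality_only(self, ethr_inputs):
        m = build_transition_matrix(ethr_inputs, 5, 75.0)
        q = ethr_inputs.life_table.lookup(75.0)
        assert m[S["well"], S["dead"]] == pytest.approx(q)
        assert m[S["well"], S["well"]] == pytest.approx(1 - q)

    def test_dead_is_absorbing(self, any_inputs):
        m = build_transition_matrix(any_inputs, 1, 70.0)
        expected = np.zeros(N_STATES)
        expected[S["dead"]] = 1.0
        np.testing.assert_array_equal(m[S["dead"]], expected)


class TestOnsetComposition:
    def test_two_cycle_pts_onset_composes_to_stated_incidence(self, any_inputs):
        """With zero background mortality, the mass reaching PTS from each
        post-DVT state over the first two cycles equals the 2-year incidence."""
        inputs = zero_mortality_inputs(any_inputs)
        lt = inputs.long_term
        targets = {
            "post_sympt_prox_dvt": lt.pts_2yr_sympt_prox_dvt,
            "post_sympt_dist_dvt": lt.pts_2yr_sympt_dist_dvt,
            "post_asympt_prox_dvt": lt.pts_2yr_asympt_prox_dvt,
            "post_asympt_dist_dvt": lt.pts_2yr_asympt_dist_dvt,
        }
        for state, expected in targets.items():
            occ = np.zeros(N_STATES)
            occ[S[state]] = 1.0
            onset = 0.0
            for k in range(2):
                occ = occ @ build_transition_matrix(inputs, k, 69.0 + k)
                onset += occ[S["pts_mildmod_y1"]] + occ[S["pts_severe_y1"]]
            assert onset == pytest.approx(expected, abs=1e-9), state

    def test_post_pe_competing_onsets_both_compose_exactly(self, any_inputs):
        """PTS and CTEPH from post-PE both reproduce their stated 2-year
        incidences despite competing (the joint conversion's purpose)."""
        inputs = zero_mortality_inputs(any_inputs)
        lt = inputs.long_term
        occ = np.zeros(N_STATES)
        occ[S["post_pe"]] = 1.0
        pts = cteph = 0.0
        for k in range(2):
            occ = occ @ build_transition_matrix(inputs, k, 69.0 + k)
            pts += occ[S["pts_mildmod_y1"]] + occ[S["pts_severe_y1"]]
            cteph += occ[S["cteph_y1"]]
        assert pts == pytest.approx(lt.pts_2yr_nonfatal_pe, abs=1e-9)
        assert cteph == pytest.approx(lt.cteph_2yr_after_pe, abs=1e-9)


class TestCohortRun:
    def test_occupancy_conservation_and_dead_monotone(self, any_inputs):
        entry = {"well": 0.9, "post_pe": 0.05, "post_sympt_prox_dvt": 0.03,
                 "disabled_post_stroke": 0.01, "dead": 0.01}
        trace = run_cohort(entry, any_inputs)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        dead = trace.occupancy[:, S["dead"]]
        assert (np.diff(dead) >= -1e-15).all()

    def test_tunnel_discipline(self, ethr_inputs):
        """Mass in a tunnel state at cycle k contributes nothing to the same
        tunnel at cycle k+1."""
        trace = run_cohort({"post_pe": 1.0}, ethr_inputs)
        for k in range(2, min(6, trace.n_cycles)):
            m = build_transition_matrix(ethr_inputs, k, trace.cycle_ages[k])
            for tun in TUNNEL_STATES:
                assert m[S[tun], S[tun]] == 0.0

    def test_all_dead_entry_zero_value(self, ethr_inputs):
        trace = run_cohort({"dead": 1.0}, ethr_inputs)
        assert trace.total_discounted_cost == 0.0
        assert trace.total_discounted_qalys == 0.0

    def test_certain_mortality_gives_one_live_cycle(self, ethr_inputs):
        lt = LifeTable(ages=np.arange(0, 111, dtype=float), qx=np.ones(111))
        trace = run_cohort({"well": 1.0}, ethr_inputs.replace(life_table=lt))
        assert trace.n_cycles == 1
        assert trace.occupancy[1, S["dead"]] == pytest.approx(1.0)

    def test_horizon_below_one_cycle_rejected(self, ethr_inputs):
        bad = ethr_inputs.replace(
            settings=replace(ethr_inputs.settings, time_horizon_years=0.5))
        with pytest.raises(ValueError):
            run_cohort({"well": 1.0}, bad)

    @pytest.mark.parametrize("half_cycle,convention",
                             [(False, "cycle-start"), (True, "midyear")])
    def test_zero_morbidity_qalys_equal_life_expectancy(self, ethr_inputs,
                                                        half_cycle, convention):
        """Utility 1, no morbidity, no discounting: lifetime QALYs equal the
        life table's own expectation under the matching accrual convention."""
        lt_zero = replace(
            ethr_inputs.long_term,
            pts_2yr_sympt_prox_dvt=0.0, pts_2yr_sympt_dist_dvt=0.0,
            pts_2yr_asympt_prox_dvt=0.0, pts_2yr_asympt_dist_dvt=0.0,
            pts_2yr_nonfatal_pe=0.0, cteph_2yr_after_pe=0.0,
        )
        utils = replace(ethr_inputs.utilities, preop=1.0, post_9mo=1.0)
        inputs = ethr_inputs.replace(
            long_term=lt_zero, utilities=utils,
            settings=replace(ethr_inputs.settings, discount_rate=0.0),
            markov_config=replace(ethr_inputs.markov_config,
                                  half_cycle_correction=half_cycle),
        )
        trace = run_cohort({"well": 1.0}, inputs)
        entry_age = inputs.cohort.start_age + 90.0 / 365.25
        expected = inputs.life_table.life_expectancy(entry_age, convention)
        assert trace.total_discounted_qalys == pytest.approx(expected, abs=1e-9)


def scalar_oracle_five_state(inputs, entry, n_cycles):
    """Hand-written scalar forward recursion on the 5-state sub-model
    {post_sympt_prox_dvt, pts_mildmod_y1, pts_severe_y1, chronic-merged,
    dead}: an independent check on the matrix engine."""
    lt = inputs.long_term
    sev = lt.prop_pts_severe
    p = 1 - math.sqrt(1 - lt.pts_2yr_sympt_prox_dvt)
    post, y1m, y1s, chronic, dead = entry
    hist = [(post, y1m, y1s, chronic, dead)]
    entry_age = inputs.cohort.start_age + 90.0 / 365.25
    for k in range(n_cycles):
        q = inputs.life_table.lookup(entry_age + k)
        s = 1 - q
        onset = p if k < 2 else 0.0
        post2 = post * s * (1 - onset)
        y1m2 = post * s * onset * (1 - sev)
        y1s2 = post * s * onset * sev
        chronic2 = chronic * s + (y1m + y1s) * s
        dead2 = dead + q * (post + y1m + y1s + chronic)
        post, y1m, y1s, chronic, dead = post2, y1m2, y1s2, chronic2, dead2
        hist.append((post, y1m, y1s, chronic, dead))
    return hist


def test_engine_matches_scalar_oracle_on_sub_model(ethr_inputs):
    trace = run_cohort({"post_sympt_prox_dvt": 1.0}, ethr_inputs)
    oracle = scalar_oracle_five_state(ethr_inputs, (1.0, 0, 0, 0, 0), 10)
    for k in range(11):
        occ = trace.occupancy[k]
        post, y1m, y1s, chronic, dead = oracle[k]
        assert occ[S["post_sympt_prox_dvt"]] == pytest.approx(post, abs=1e-12)
        assert occ[S["pts_mildmod_y1"]] == pytest.approx(y1m, abs=1e-12)
        assert occ[S["pts_severe_y1"]] == pytest.approx(y1s, abs=1e-12)
        assert (occ[S["pts_mildmod_chronic"]] + occ[S["pts_severe_chronic"]]
                == pytest.approx(chronic, abs=1e-12))
        assert occ[S["dead"]] == pytest.approx(dead, abs=1e-12)


def test_fast_components_match_cohort_traces(any_inputs):
    """The shared-matrix aggregation used by the PSA equals per-strategy
    cohort traces."""
    from vtecea.acute import evaluate_acute
    from vtecea.pipeline import _entry_array

    comp = markov_components(any_inputs)
    for strategy in (any_inputs.comparator, "no_prophylaxis"):
        acute = evaluate_acute(any_inputs, strategy)
        trace = run_cohort(acute.entry_distribution, any_inputs)
        entry = _entry_array(acute.entry_distribution)
        assert float(entry @ comp.qaly_value) == pytest.approx(
            trace.total_discounted_qalys, abs=1e-9)
        assert float(entry @ comp.cost_value) == pytest.approx(
            trace.total_discounted_cost, abs=1e-6)
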