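"""Synthetic inputs: life tables, random parameter sets, known-answer panels.

Everything the pipeline consumes can be generated here without downloads.
The Gompertz–Makeham life table is a synthetic stand-in (no national life
table edition is prescribed by the model inputs); its default parameters are
calibrated so that life expectancy at age 68.7 is roughly 17 years, a
plausible figure for an elective arthroplasty cohort.  Real life tables can
be supplied as CSV (columns ``age, qx``) instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .types import (
    BaselineRiskSet,
    CohortSpec,
    CostSet,
    EconSettings,
    EventRisk,
    LifeTable,
    LongTermRiskSet,
    ModelInputs,
    StrategyRisks,
    StrategySpec,
    UtilitySet,
)

#: Gompertz–Makeham defaults (synthetic, non-tabulated): q(x) = a + b·exp(c·x)
MAKEHAM_A = 1.0e-4
GOMPERTZ_B = 1.8e-5
GOMPERTZ_C = 0.0975
TERMINAL_AGE = 110


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs for random-but-valid input generation."""

    seed: int = 0
    makeham_a: float = MAKEHAM_A
    gompertz_b: float = GOMPERTZ_B
    gompertz_c: float = GOMPERTZ_C
    n_strategies: int = 8
    rr_log_sd: float = 0.5          # strategy effects: lognormal around 1
    cost_range: tuple = (0.0, 400.0)
    noise_se_frac: float = 0.2      # SE as a fraction of the mean
    start_age: float = 68.7


def make_life_table(
    a: float = MAKEHAM_A,
    b: float = GOMPERTZ_B,
    c: float = GOMPERTZ_C,
    terminal_age: int = TERMINAL_AGE,
) -> LifeTable:
    """Annual death probabilities q(x) = min(1, a + b·exp(c·x)) on 0..terminal.

    The terminal age carries q = 1 so cohort simulations always absorb.
    """
    if a < 0 or b < 0:
        raise ValueError("life-table parameters must be non-negative")
    ages = np.arange(0, terminal_age + 1, dtype=float)
    qx = np.minimum(1.0, a + b * np.exp(c * ages))
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def make_inputs(spec: SyntheticSpec = SyntheticSpec()) -> ModelInputs:
    """A random, internally consistent ModelInputs (deterministic under seed).

    Strategy event risks are the comparator baseline scaled by lognormal
    relative effects; utilities are ordered (preop < 9-month); costs are
    uniform in the configured range.  The output always passes
    :meth:`ModelInputs.validate`.
    """
    rng = np.random.default_rng(spec.seed)

    cohort = CohortSpec(
        start_age=spec.start_age,
        proportion_male=float(rng.uniform(0.3, 0.7)),
        mean_bmi=float(rng.uniform(24, 34)),
        population_label="synthetic",
    )
    baseline = BaselineRiskSet(
        total_dvt=float(rng.uniform(0.03, 0.15)),
        symptomatic_dvt=float(rng.uniform(0.002, 0.02)),
        prop_symptomatic_proximal=float(rng.uniform(0.2, 0.9)),
        prop_asymptomatic_proximal=float(rng.uniform(0.05, 0.4)),
        nonfatal_pe=float(rng.uniform(0.002, 0.01)),
        pe_case_fatality=float(rng.uniform(0.05, 0.25)),
        mb_surgical_site=float(rng.uniform(0.002, 0.03)),
        mb_gi_ich=float(rng.uniform(0.001, 0.01)),
        mb_other=float(rng.uniform(0.0005, 0.005)),
        crnmb=float(rng.uniform(0.01, 0.05)),
        wound_haematoma_frac_of_crnmb=float(rng.uniform(0.1, 0.3)),
        hit=float(rng.uniform(0.0005, 0.01)),
    )
    # keep symptomatic <= total
    if baseline.symptomatic_dvt > baseline.total_dvt:
        baseline = BaselineRiskSet(
            **{**baseline.__dict__, "symptomatic_dvt": baseline.total_dvt / 4}
        )

    names = ["no_prophylaxis"] + [f"strategy_{i:02d}" for i in range(1, spec.n_strategies)]
    strategies = [
        StrategySpec(
            name=n,
            label=n.replace("_", " "),
            pharm_duration_days=None if n == "no_prophylaxis" else float(rng.integers(7, 36)),
        )
        for n in names
    ]

    absolute_risks = {}
    for n in names:
        effects = np.exp(rng.normal(0.0, spec.rr_log_sd, size=6))
        base_vals = np.array([
            baseline.total_dvt, baseline.nonfatal_pe, baseline.mb_gi_ich,
            baseline.mb_surgical_site, baseline.mb_other, baseline.crnmb,
        ])
        vals = np.minimum(base_vals * effects, 0.95)
        absolute_risks[n] = StrategyRisks(
            dvt=EventRisk(float(vals[0])), pe=EventRisk(float(vals[1])),
            gi_ich=EventRisk(float(vals[2])), ssb=EventRisk(float(vals[3])),
            other_mb=EventRisk(float(vals[4])), crnmb=EventRisk(float(vals[5])),
        )

    preop = float(rng.uniform(0.2, 0.5))
    post = float(rng.uniform(preop + 0.05, 0.9))
    utilities = UtilitySet(
        preop=preop, post_9mo=post, post_9mo_se=post * spec.noise_se_frac / 2,
        sympt_prox_dvt_rel=0.14, sympt_dist_dvt_rel=0.14,
        sympt_dist_dvt_untreated_rel=0.07, nonfatal_pe_rel=0.19,
        warfarin_treated_abs=0.012, mb_rel=0.32, ich_stroke_rel=0.65,
        pre_revision=preop, post_revision=post * 0.9, post_reoperation=post * 0.9,
        crnmb_abs=0.03, ssi_rel=0.66, post_infected_revision_rel=0.30,
        hit_abs=0.0712, hit_thrombosis_rel=0.165, hit_mb_rel=0.32,
        post_amputation_abs=0.28, post_stroke_rel=0.10,
        pts_mildmod_abs=0.02, pts_severe_abs=0.07,
        cteph_y1_rel=0.26, cteph_y2_improvement_rel=0.22,
    )

    lo, hi = spec.cost_range
    strategy_pharm = {
        n: 0.0 if n == "no_prophylaxis" else float(rng.uniform(lo, hi)) for n in names
    }
    strategy_mech = {n: 0.0 for n in names}
    event_names = ["sympt_prox_dvt", "sympt_dist_dvt", "nonfatal_pe",
                   "ssb_return_theatre", "gi_with_intervention",
                   "gi_without_intervention", "stroke_admission",
                   "stroke_acute_90d", "crnmb", "ssi_medical",
                   "revision_infected", "hit", "amputation_acute"]
    state_names = ["stroke_y1_dependent", "stroke_y1_independent",
                   "stroke_y2_dependent", "stroke_y2_independent",
                   "amputation_y1", "amputation_y2", "pts_mildmod_y1",
                   "pts_mildmod_y2", "pts_severe_y1", "pts_severe_y2",
                   "cteph_operable_y1", "cteph_recurrent_y1",
                   "cteph_inoperable_y1", "cteph_recurrent_y2",
                   "cteph_chronic_y2", "cteph_treated"]
    costs = CostSet(
        strategy_pharm=strategy_pharm,
        strategy_mech=strategy_mech,
        event={n: float(rng.uniform(100, 20_000)) for n in event_names},
        state={n: float(rng.uniform(100, 30_000)) for n in state_names},
    )

    long_term = LongTermRiskSet(
        pts_2yr_sympt_prox_dvt=float(rng.uniform(0.2, 0.5)),
        pts_2yr_sympt_dist_dvt=float(rng.uniform(0.05, 0.15)),
        pts_2yr_asympt_prox_dvt=float(rng.uniform(0.08, 0.2)),
        pts_2yr_asympt_dist_dvt=float(rng.uniform(0.01, 0.06)),
        pts_2yr_nonfatal_pe=float(rng.uniform(0.08, 0.2)),
        prop_pts_severe=float(rng.uniform(0.1, 0.4)),
        cteph_2yr_after_pe=float(rng.uniform(0.01, 0.05)),
        cteph_mortality=float(rng.uniform(0.1, 0.3)),
    )

    inputs = ModelInputs(
        cohort=cohort,
        strategies=strategies,
        baseline=baseline,
        absolute_risks=absolute_risks,
        utilities=utilities,
        costs=costs,
        long_term=long_term,
        settings=EconSettings(),
        life_table=make_life_table(spec.makeham_a, spec.gompertz_b, spec.gompertz_c),
        comparator="no_prophylaxis",
    )
    inputs.validate()
    return inputs


# ---------------------------------------------------------------------------
# known-answer panels for the CEA oracles


def _brute_force_dominated(points: np.ndarray) -> list[bool]:
    """Exhaustive pairwise strict-dominance check on (cost, qaly) rows."""
    n = len(points)
    out = []
    for i in range(n):
        ci, qi = points[i]
        dominated = any(
            (points[j][0] <= ci and points[j][1] >= qi)
            and (points[j][0] < ci or points[j][1] > qi)
            for j in range(n) if j != i
        )
        out.append(dominated)
    return out


def _brute_force_extended(points: np.ndarray, dominated: list[bool]) -> list[bool]:
    """Above-hull test: a surviving point is extendedly dominated if some
    convex combination of two other surviving points gives more QALYs at
    lower-or-equal cost (segment test, exhaustive over pairs)."""
    idx = [i for i in range(len(points)) if not dominated[i]]
    ext = [False] * len(points)
    for i in idx:
        ci, qi = points[i]
        for a, b in itertools.combinations([j for j in idx if j != i], 2):
            (ca, qa), (cb, qb) = points[a], points[b]
            if min(qa, qb) <= qi <= max(qa, qb) and qa != qb:
                t = (qi - qa) / (qb - qa)
                blend_cost = ca + t * (cb - ca)
                if blend_cost < ci - 1e-12:
                    ext[i] = True
                    break
    return ext


def make_known_answer_panel(kind: str, seed: int = 0, n: int = 6):
    """A constructed (cost, QALY) panel with its answer computed by brute force.

    kind="dominance": contains at least one strictly dominated point; the
    stored answer is the exhaustive pairwise dominance status.
    kind="extended_dominance": contains at least one above-hull point; the
    stored answer is (dominated, extendedly_dominated) statuses.
    kind="nmb_rank": stored answer is the argsort ranking of NMB at
    lambda = 20,000 (ties broken by cost then name order).
    """
    rng = np.random.default_rng(seed)
    if kind == "dominance":
        points = np.column_stack([
            rng.uniform(0, 2000, size=n), rng.uniform(8, 11, size=n)
        ])
        # plant a strictly dominated point: costlier and less effective than row 0
        points[1] = [points[0][0] + 100.0, points[0][1] - 0.5]
        return points, _brute_force_dominated(points)
    if kind == "extended_dominance":
        # anchor frontier then plant a point above the chord of rows 0 and 2
        points = np.array([
            [0.0, 9.0],
            [600.0, 9.5],     # above the (0,9)–(800,10) chord -> extendedly dominated
            [800.0, 10.0],
            [2000.0, 10.4],
        ])
        extra = np.column_stack([
            rng.uniform(0, 2500, size=max(0, n - 4)),
            rng.uniform(8.5, 10.5, size=max(0, n - 4)),
        ])
        points = np.vstack([points, extra])
        dominated = _brute_force_dominated(points)
        extended = _brute_force_extended(points, dominated)
        return points, (dominated, extended)
    if kind == "nmb_rank":
        points = np.column_stack([
            rng.uniform(0, 2000, size=n), rng.uniform(8, 11, size=n)
        ])
        lam = 20_000.0
        nmb = points[:, 1] * lam - points[:, 0]
        order = sorted(range(n), key=lambda i: (-nmb[i], points[i][0], i))
        ranks = [0] * n
        for pos, i in enumerate(order, start=1):
            ranks[i] = pos
        return points, ranks
    raise ValueError(f"unknown panel kind {kind!r}")
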