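"""Loading, validation and derivation of model parameters.

The packaged fixtures ``ethr_inputs.csv`` and ``etkr_inputs.csv`` transcribe
the published parameter tables for the two populations (strategy panel and
durations, baseline 90-day risks, per-strategy absolute event risks with 95%
credible intervals, utilities, intervention and event costs, long-term event
risks, economic settings).  A user config may be either such a CSV, or a
JSON/YAML document ``{"table": <csv path>, "overrides": {"block.name": value}}``.
"""

from __future__ import annotations

import json
import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import (
    COMPARATOR,
    BaselineRiskSet,
    CohortSpec,
    CostSet,
    EconSettings,
    EventRisk,
    LifeTable,
    LongTermRiskSet,
    MarkovConfig,
    ModelInputs,
    StrategyRisks,
    StrategySpec,
    TreeConfig,
    UtilitySet,
    ValidationError,
)

log = logging.getLogger(__name__)

_POPULATION_FILES = {"ethr": "ethr_inputs.csv", "etkr": "etkr_inputs.csv"}

FIXTURE_COLUMNS = ["block", "name", "value", "se", "low95", "high95", "source"]


def _normalize_population(population: str) -> str:
    key = population.strip().lower().replace("-", "")
    if key not in _POPULATION_FILES:
        raise ValidationError(
            f"unknown population {population!r}; expected 'eTHR' or 'eTKR'"
        )
    return key


def packaged_fixture_path(population: str):
    """Importlib handle on the packaged parameter table for a population."""
    return resources.files("vtecea.data") / _POPULATION_FILES[_normalize_population(population)]


def read_parameter_table(path_or_buffer) -> pd.DataFrame:
    df = pd.read_csv(path_or_buffer, dtype={"block": str, "name": str, "source": str},
                     float_precision="round_trip")
    missing = set(FIXTURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"parameter table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# derivations


def derive_asymptomatic_dvt(symptomatic: float, asympt_to_sympt_ratio: float) -> float:
    """Asymptomatic DVT risk from the symptomatic risk and the observed
    asymptomatic:symptomatic ratio; total DVT = symptomatic + result."""
    if not (0.0 <= symptomatic <= 1.0):
        raise ValidationError(f"symptomatic must lie in [0, 1], got {symptomatic}")
    if asympt_to_sympt_ratio < 0:
        raise ValidationError("asympt_to_sympt_ratio must be >= 0")
    asympt = symptomatic * asympt_to_sympt_ratio
    if symptomatic + asympt > 1.0 + 1e-12:
        raise ValidationError(
            f"derived total DVT risk {symptomatic + asympt:.4f} exceeds 1; "
            "inconsistent asymptomatic ratio"
        )
    return asympt


def apply_relative_risk(baseline: float, rr: float) -> float:
    """Absolute risk = baseline × RR, capped at 1 (capping logged)."""
    if not (0.0 <= baseline <= 1.0):
        raise ValidationError(f"baseline must lie in [0, 1], got {baseline}")
    if rr <= 0:
        raise ValidationError(f"relative risk must be > 0, got {rr}")
    p = baseline * rr
    if p > 1.0:
        warnings.warn(
            f"relative risk {rr} on baseline {baseline} gives {p:.4f}; capped at 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return p


def apply_odds_ratio(baseline: float, or_value: float) -> float:
    """Absolute risk from baseline risk and odds ratio on the odds scale."""
    if not (0.0 < baseline < 1.0):
        raise ValidationError(
            f"baseline must lie strictly in (0, 1) for odds, got {baseline}"
        )
    if or_value <= 0:
        raise ValidationError(f"odds ratio must be > 0, got {or_value}")
    odds = or_value * baseline / (1.0 - baseline)
    return odds / (1.0 + odds)


def strategy_total_cost(strategy_name: str, costs: CostSet) -> float:
    """Total intervention cost: pharmacological + mechanical components."""
    try:
        return costs.strategy_pharm[strategy_name] + costs.strategy_mech[strategy_name]
    except KeyError as exc:
        raise KeyError(f"unknown strategy {strategy_name!r} in cost set") from exc


# ---------------------------------------------------------------------------
# loading


def _block_dict(df: pd.DataFrame, block: str) -> dict[str, float]:
    sub = df[df["block"] == block]
    return {row["name"]: row["value"] for _, row in sub.iterrows()}


def _build_inputs(df: pd.DataFrame, population: str) -> ModelInputs:
    from .synthetic import make_life_table  # deferred: synthetic depends on types only

    cohort_rows = df[df["block"] == "cohort"].set_index("name")
    label = cohort_rows.loc["population_label", "source"]
    cohort = CohortSpec(
        start_age=float(cohort_rows.loc["start_age", "value"]),
        start_age_sd=float(cohort_rows.loc["start_age", "se"]),
        proportion_male=float(cohort_rows.loc["proportion_male", "value"]),
        mean_bmi=float(cohort_rows.loc["mean_bmi", "value"]),
        population_label=label,
    )

    base = _block_dict(df, "baseline")
    other = _block_dict(df, "other")
    baseline = BaselineRiskSet(
        total_dvt=base["total_dvt"],
        symptomatic_dvt=base["symptomatic_dvt"],
        prop_symptomatic_proximal=base["prop_symptomatic_proximal"],
        prop_asymptomatic_proximal=base["prop_asymptomatic_proximal"],
        nonfatal_pe=base["nonfatal_pe"],
        pe_case_fatality=base["pe_case_fatality"],
        mb_surgical_site=base["mb_surgical_site"],
        mb_gi_ich=base["mb_gi_ich"],
        mb_other=base["mb_other"],
        crnmb=base["crnmb"],
        wound_haematoma_frac_of_crnmb=base["wound_haematoma_frac_of_crnmb"],
        hit=base["hit"],
    )
    stored_asympt = base.get("asymptomatic_dvt")
    if stored_asympt is not None and not np.isclose(
        stored_asympt, baseline.asymptomatic_dvt, atol=5e-4
    ):
        raise ValidationError(
            f"stored asymptomatic DVT {stored_asympt} inconsistent with "
            f"total - symptomatic = {baseline.asymptomatic_dvt:.4f}"
        )

    labels = {
        row["name"]: row["source"]
        for _, row in df[df["block"] == "strategy_label"].iterrows()
    }
    dur_p = _block_dict(df, "strategy_duration_pharm")
    dur_m = _block_dict(df, "strategy_duration_mech")
    strategies = [
        StrategySpec(
            name=slug,
            label=labels[slug],
            pharm_duration_days=dur_p.get(slug),
            mech_duration_days=dur_m.get(slug),
        )
        for slug in labels
    ]

    flags = set(df[df["block"] == "flag_proportional"]["name"])
    risk_blocks = {
        "dvt": "risk_dvt", "pe": "risk_pe", "gi_ich": "risk_gi_ich",
        "ssb": "risk_ssb", "other_mb": "risk_other_mb", "crnmb": "risk_crnmb",
    }
    risk_rows = {
        b: df[df["block"] == b].set_index("name") for b in risk_blocks.values()
    }
    absolute_risks = {}
    for slug in labels:
        kwargs = {}
        for field_name, block in risk_blocks.items():
            row = risk_rows[block].loc[slug]
            low = None if pd.isna(row["low95"]) else float(row["low95"])
            high = None if pd.isna(row["high95"]) else float(row["high95"])
            kwargs[field_name] = EventRisk(float(row["value"]), low, high)
        absolute_risks[slug] = StrategyRisks(
            proportionality_flag=slug in flags, **kwargs
        )

    util_rows = df[df["block"] == "utility"].set_index("name")
    u = {name: float(row["value"]) for name, row in util_rows.iterrows()}
    utilities = UtilitySet(
        preop=u["preop"],
        post_9mo=u["post_9mo"],
        post_9mo_se=float(util_rows.loc["post_9mo", "se"]),
        sympt_prox_dvt_rel=u["sympt_prox_dvt_rel"],
        sympt_dist_dvt_rel=u["sympt_dist_dvt_rel"],
        sympt_dist_dvt_untreated_rel=u["sympt_dist_dvt_untreated_rel"],
        nonfatal_pe_rel=u["nonfatal_pe_rel"],
        warfarin_treated_abs=u["warfarin_treated_abs"],
        mb_rel=u["mb_rel"],
        ich_stroke_rel=u["ich_stroke_rel"],
        pre_revision=u["pre_revision"],
        post_revision=u["post_revision"],
        post_reoperation=u["post_reoperation"],
        crnmb_abs=u["crnmb_abs"],
        ssi_rel=u["ssi_rel"],
        post_infected_revision_rel=u["post_infected_revision_rel"],
        hit_abs=u["hit_abs"],
        hit_thrombosis_rel=u["hit_thrombosis_rel"],
        hit_mb_rel=u["hit_mb_rel"],
        post_amputation_abs=u["post_amputation_abs"],
        post_stroke_rel=u["post_stroke_rel"],
        pts_mildmod_abs=u["pts_mildmod_abs"],
        pts_severe_abs=u["pts_severe_abs"],
        cteph_y1_rel=u["cteph_y1_rel"],
        cteph_y2_improvement_rel=u["cteph_y2_improvement_rel"],
    )

    costs = CostSet(
        strategy_pharm=_block_dict(df, "strategy_cost_pharm"),
        strategy_mech=_block_dict(df, "strategy_cost_mech"),
        event=_block_dict(df, "cost_event"),
        state=_block_dict(df, "cost_state"),
    )

    lt = _block_dict(df, "long_term")
    long_term = LongTermRiskSet(
        pts_2yr_sympt_prox_dvt=lt["pts_2yr_sympt_prox_dvt"],
        pts_2yr_sympt_dist_dvt=lt["pts_2yr_sympt_dist_dvt"],
        pts_2yr_asympt_prox_dvt=lt["pts_2yr_asympt_prox_dvt"],
        pts_2yr_asympt_dist_dvt=lt["pts_2yr_asympt_dist_dvt"],
        pts_2yr_nonfatal_pe=lt["pts_2yr_nonfatal_pe"],
        prop_pts_severe=lt["prop_pts_severe"],
        cteph_2yr_after_pe=lt["cteph_2yr_after_pe"],
        cteph_mortality=lt["cteph_mortality"],
    )

    s = _block_dict(df, "setting")
    horizon = s.get("time_horizon_years")
    settings = EconSettings(
        threshold_lambda=s["threshold_lambda"],
        discount_rate=s["discount_rate"],
        time_horizon_years=None if horizon is None or pd.isna(horizon) else float(horizon),
        cycle_length_years=s["cycle_length_years"],
        price_year=int(s["price_year"]),
        psa_iterations=int(s["psa_iterations"]),
    )

    cfg = _block_dict(df, "config")
    tree_config = TreeConfig(
        return_to_theatre_after_ssb=other["return_to_theatre_after_ssb"],
        gi_intervention_frac=other["gi_intervention_frac"],
        ssi_given_haematoma=other["ssi_given_haematoma"],
        surgical_mgmt_given_ssi=other["surgical_mgmt_given_ssi"],
        revision_vs_return_ratio=other["revision_vs_return_ratio"],
        fatal_mb_prob=cfg.get("fatal_mb_prob", 0.0),
        hit_frac_success=cfg.get("hit_frac_success", 0.94),
        hit_frac_thrombosis=cfg.get("hit_frac_thrombosis", 0.03),
        hit_frac_mb=cfg.get("hit_frac_mb", 0.02),
        hit_frac_death=cfg.get("hit_frac_death", 0.01),
        hit_amputation_prob=cfg.get("hit_amputation_prob", 0.01),
        gi_share_of_gi_ich=cfg.get("gi_share_of_gi_ich", 0.5),
    )
    markov_config = MarkovConfig(
        cteph_frac_operable=cfg.get("cteph_frac_operable", 1 / 3),
        cteph_frac_inoperable=cfg.get("cteph_frac_inoperable", 1 / 3),
        cteph_frac_recurrent=cfg.get("cteph_frac_recurrent", 1 / 3),
        stroke_dependent_frac=cfg.get("stroke_dependent_frac", 0.25),
    )

    lt_rows = df[df["block"] == "life_table"]
    if len(lt_rows):
        ages = lt_rows["name"].astype(float).to_numpy()
        qx = lt_rows["value"].astype(float).to_numpy()
        order = np.argsort(ages)
        life_table = LifeTable(ages=ages[order], qx=qx[order])
    else:
        life_table = make_life_table()

    meta = df[df["block"] == "meta"].set_index("name")
    comparator = (meta.loc["comparator", "source"]
                  if "comparator" in meta.index else COMPARATOR)

    param_se = {
        f"{row['block']}.{row['name']}": float(row["se"])
        for _, row in df.iterrows()
        if not pd.isna(row["se"]) and row["block"] not in (
            "cohort", "strategy_cost_pharm", "strategy_cost_mech")
    }

    inputs = ModelInputs(
        cohort=cohort,
        strategies=strategies,
        baseline=baseline,
        absolute_risks=absolute_risks,
        utilities=utilities,
        costs=costs,
        long_term=long_term,
        settings=settings,
        life_table=life_table,
        tree_config=tree_config,
        markov_config=markov_config,
        comparator=comparator,
        param_se=param_se,
    )
    inputs.validate()
    return inputs


def load_inputs(
    config_path: Optional[Union[str, Path]] = None, population: str = "eTHR"
) -> ModelInputs:
    """Load and validate the full parameter set for one population.

    ``config_path=None`` loads the packaged fixture.  A ``.csv`` path is read
    as a parameter table in the published schema; a ``.json``/``.yaml`` path
    is read as a config document with optional ``table`` and ``overrides``
    keys, the latter mapping ``"block.name"`` to replacement values.
    """
    overrides: dict[str, float] = {}
    table_path = None
    if config_path is not None:
        p = Path(config_path)
        if not p.exists():
            raise FileNotFoundError(p)
        if p.suffix == ".csv":
            table_path = p
        else:
            if p.suffix in (".yaml", ".yml"):
                import yaml

                doc = yaml.safe_load(p.read_text())
            else:
                doc = json.loads(p.read_text())
            table_path = doc.get("table")
            overrides = doc.get("overrides", {})
            population = doc.get("population", population)

    if table_path is None:
        with resources.as_file(packaged_fixture_path(population)) as fp:
            df = read_parameter_table(fp)
    else:
        df = read_parameter_table(table_path)

    for key, value in overrides.items():
        block, name = key.split(".", 1)
        mask = (df["block"] == block) & (df["name"] == name)
        if not mask.any():
            df = pd.concat(
                [df, pd.DataFrame([{"block": block, "name": name, "value": value}])],
                ignore_index=True,
            )
        else:
            df.loc[mask, "value"] = value

    return _build_inputs(df, population)


# ---------------------------------------------------------------------------
# writing


def write_inputs(inputs: ModelInputs, path: Union[str, Path]) -> None:
    """Serialize a ModelInputs back to the CSV parameter-table schema.

    ``load_inputs(write_inputs(x)) == x`` field-for-field (the round-trip
    contract); the life table is embedded so the output is self-contained.
    """
    rows: list[dict] = []

    def add(block, name, value=None, se=None, low=None, high=None, source=""):
        rows.append({
            "block": block, "name": name, "value": value, "se": se,
            "low95": low, "high95": high, "source": source,
        })

    c = inputs.cohort
    add("cohort", "population_label", source=c.population_label)
    add("cohort", "start_age", c.start_age, se=c.start_age_sd)
    add("cohort", "proportion_male", c.proportion_male)
    add("cohort", "mean_bmi", c.mean_bmi)

    def se_of(key):
        return inputs.param_se.get(key)

    b = inputs.baseline
    for name in ("total_dvt", "symptomatic_dvt", "prop_symptomatic_proximal",
                 "prop_asymptomatic_proximal", "nonfatal_pe", "pe_case_fatality",
                 "mb_surgical_site", "mb_gi_ich", "mb_other", "crnmb",
                 "wound_haematoma_frac_of_crnmb", "hit"):
        add("baseline", name, getattr(b, name), se=se_of(f"baseline.{name}"))

    t = inputs.tree_config
    add("other", "return_to_theatre_after_ssb", t.return_to_theatre_after_ssb)
    add("other", "gi_intervention_frac", t.gi_intervention_frac)
    add("other", "ssi_given_haematoma", t.ssi_given_haematoma,
        se=se_of("other.ssi_given_haematoma"))
    add("other", "surgical_mgmt_given_ssi", t.surgical_mgmt_given_ssi,
        se=se_of("other.surgical_mgmt_given_ssi"))
    add("other", "revision_vs_return_ratio", t.revision_vs_return_ratio)
    for name in ("fatal_mb_prob", "hit_frac_success", "hit_frac_thrombosis",
                 "hit_frac_mb", "hit_frac_death", "hit_amputation_prob",
                 "gi_share_of_gi_ich"):
        add("config", name, getattr(t, name))
    m = inputs.markov_config
    for name in ("cteph_frac_operable", "cteph_frac_inoperable",
                 "cteph_frac_recurrent", "stroke_dependent_frac"):
        add("config", name, getattr(m, name))

    lt = inputs.long_term
    for name in ("pts_2yr_sympt_prox_dvt", "pts_2yr_sympt_dist_dvt",
                 "pts_2yr_asympt_prox_dvt", "pts_2yr_asympt_dist_dvt",
                 "pts_2yr_nonfatal_pe", "prop_pts_severe",
                 "cteph_2yr_after_pe", "cteph_mortality"):
        add("long_term", name, getattr(lt, name), se=se_of(f"long_term.{name}"))

    for name, value in inputs.costs.event.items():
        add("cost_event", name, value)
    for name, value in inputs.costs.state.items():
        add("cost_state", name, value)

    u = inputs.utilities
    add("utility", "preop", u.preop)
    add("utility", "post_9mo", u.post_9mo, se=u.post_9mo_se)
    for name in ("sympt_prox_dvt_rel", "sympt_dist_dvt_rel",
                 "sympt_dist_dvt_untreated_rel", "nonfatal_pe_rel",
                 "warfarin_treated_abs", "mb_rel", "ich_stroke_rel",
                 "pre_revision", "post_revision", "post_reoperation",
                 "crnmb_abs", "ssi_rel", "post_infected_revision_rel",
                 "hit_abs", "hit_thrombosis_rel", "hit_mb_rel",
                 "post_amputation_abs", "post_stroke_rel", "pts_mildmod_abs",
                 "pts_severe_abs", "cteph_y1_rel", "cteph_y2_improvement_rel"):
        add("utility", name, getattr(u, name), se=se_of(f"utility.{name}"))

    add("meta", "comparator", source=inputs.comparator)
    s = inputs.settings
    add("setting", "threshold_lambda", s.threshold_lambda)
    add("setting", "discount_rate", s.discount_rate)
    add("setting", "cycle_length_years", s.cycle_length_years)
    add("setting", "time_horizon_years", s.time_horizon_years)
    add("setting", "price_year", s.price_year)
    add("setting", "psa_iterations", s.psa_iterations)

    for spec in inputs.strategies:
        add("strategy_label", spec.name, source=spec.label)
        if spec.pharm_duration_days is not None:
            add("strategy_duration_pharm", spec.name, spec.pharm_duration_days)
        if spec.mech_duration_days is not None:
            add("strategy_duration_mech", spec.name, spec.mech_duration_days)
        add("strategy_cost_pharm", spec.name, inputs.costs.strategy_pharm[spec.name])
        add("strategy_cost_mech", spec.name, inputs.costs.strategy_mech[spec.name])
        r = inputs.absolute_risks[spec.name]
        for field_name, block in (("dvt", "risk_dvt"), ("pe", "risk_pe"),
                                  ("gi_ich", "risk_gi_ich"), ("ssb", "risk_ssb"),
                                  ("other_mb", "risk_other_mb"),
                                  ("crnmb", "risk_crnmb")):
            er = getattr(r, field_name)
            add(block, spec.name, er.value, low=er.low95, high=er.high95)
        if r.proportionality_flag:
            add("flag_proportional", spec.name, 1)

    for age, qx in zip(inputs.life_table.ages, inputs.life_table.qx):
        add("life_table", str(age), qx)

    # %.17g keeps every float exactly recoverable (round-trip contract)
    pd.DataFrame(rows, columns=FIXTURE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")
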