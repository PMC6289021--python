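"""Domain types for the VTE-prophylaxis cost-utility model.

One :class:`ModelInputs` instance holds everything a single population's
analysis needs: cohort characteristics, the strategy panel, baseline 90-day
event risks, per-strategy absolute event risks, utilities, costs, long-term
(post-90-day) event risks, economic settings and a life table.

All probabilities are plain fractions (0.0554, not 5.54%); all costs are GBP
at 2016 prices; utilities are EQ-5D-3L index values (minimum −0.594).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

EQ5D_FLOOR = -0.594
DAYS_PER_YEAR = 365.25

#: slug of the model comparator strategy in both populations
COMPARATOR = "lmwh_std_std_aes"


class ValidationError(ValueError):
    """A parameter violates its domain constraint; message names the field."""


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Who enters the model: a surgical cohort defined by age, sex mix, BMI."""

    start_age: float
    proportion_male: float
    mean_bmi: float
    population_label: str  # "eTHR" or "eTKR"
    start_age_sd: float = 0.0

    def validate(self) -> None:
        if not (0.0 < self.start_age < 110.0):
            raise ValidationError(f"start_age out of range: {self.start_age}")
        _check_prob(self.proportion_male, "proportion_male")


@dataclass(frozen=True)
class StrategySpec:
    """One prophylaxis strategy: pharmacological and/or mechanical components.

    ``name`` is a normalized lower-case slug used as the identity key
    throughout the package; ``label`` preserves the display name.
    """

    name: str
    label: str
    pharm_duration_days: Optional[float] = None
    mech_duration_days: Optional[float] = None

    def validate(self) -> None:
        if self.name != "no_prophylaxis":
            if self.pharm_duration_days is None and self.mech_duration_days is None:
                raise ValidationError(
                    f"strategy {self.name!r} has neither a pharmacological nor "
                    "a mechanical component"
                )
        for d in (self.pharm_duration_days, self.mech_duration_days):
            if d is not None and d <= 0:
                raise ValidationError(f"strategy {self.name!r}: duration_days must be > 0")


@dataclass(frozen=True)
class BaselineRiskSet:
    """90-day baseline event risks for the comparator (LMWH std,std + AES)."""

    total_dvt: float
    symptomatic_dvt: float
    prop_symptomatic_proximal: float
    prop_asymptomatic_proximal: float
    nonfatal_pe: float
    pe_case_fatality: float
    mb_surgical_site: float
    mb_gi_ich: float
    mb_other: float
    crnmb: float
    wound_haematoma_frac_of_crnmb: float
    hit: float

    @property
    def asymptomatic_dvt(self) -> float:
        return self.total_dvt - self.symptomatic_dvt

    def validate(self) -> None:
        for f_name in (
            "total_dvt", "symptomatic_dvt", "prop_symptomatic_proximal",
            "prop_asymptomatic_proximal", "nonfatal_pe", "pe_case_fatality",
            "mb_surgical_site", "mb_gi_ich", "mb_other", "crnmb",
            "wound_haematoma_frac_of_crnmb", "hit",
        ):
            _check_prob(getattr(self, f_name), f_name)
        if self.symptomatic_dvt > self.total_dvt:
            raise ValidationError("symptomatic_dvt exceeds total_dvt")


@dataclass(frozen=True)
class EventRisk:
    """An absolute probability with an optional 95% credible interval."""

    value: float
    low95: Optional[float] = None
    high95: Optional[float] = None

    def validate(self, name: str) -> None:
        _check_prob(self.value, name)
        if self.low95 is not None and self.high95 is not None:
            if not (self.low95 <= self.value <= self.high95 or
                    np.isclose(self.low95, self.value) or np.isclose(self.high95, self.value)):
                raise ValidationError(f"{name}: CrI does not bracket the point value")


@dataclass(frozen=True)
class StrategyRisks:
    """Per-strategy absolute 90-day risks of the six tree-level events."""

    dvt: EventRisk
    pe: EventRisk
    gi_ich: EventRisk
    ssb: EventRisk
    other_mb: EventRisk
    crnmb: EventRisk
    proportionality_flag: bool = False

    def validate(self, strategy: str) -> None:
        for f_name in ("dvt", "pe", "gi_ich", "ssb", "other_mb", "crnmb"):
            getattr(self, f_name).validate(f"{strategy}.{f_name}")


@dataclass(frozen=True)
class UtilitySet:
    """Utility anchors and event/state (dis)utilities.

    ``*_rel`` values are relative fractions multiplying the baseline
    trajectory; ``*_abs`` values are absolute EQ-5D decrements.
    """

    preop: float
    post_9mo: float
    post_9mo_se: float
    sympt_prox_dvt_rel: float
    sympt_dist_dvt_rel: float
    sympt_dist_dvt_untreated_rel: float
    nonfatal_pe_rel: float
    warfarin_treated_abs: float
    mb_rel: float
    ich_stroke_rel: float
    pre_revision: float
    post_revision: float
    post_reoperation: float
    crnmb_abs: float
    ssi_rel: float
    post_infected_revision_rel: float
    hit_abs: float
    hit_thrombosis_rel: float
    hit_mb_rel: float
    post_amputation_abs: float
    post_stroke_rel: float
    pts_mildmod_abs: float
    pts_severe_abs: float
    cteph_y1_rel: float
    cteph_y2_improvement_rel: float

    def validate(self) -> None:
        for f_name in ("preop", "post_9mo", "pre_revision", "post_revision",
                       "post_reoperation"):
            v = getattr(self, f_name)
            if not (EQ5D_FLOOR <= v <= 1.0):
                raise ValidationError(f"{f_name} outside EQ-5D index bounds: {v}")
        for f_name in ("sympt_prox_dvt_rel", "sympt_dist_dvt_rel", "nonfatal_pe_rel",
                       "mb_rel", "ich_stroke_rel", "ssi_rel", "post_stroke_rel",
                       "post_infected_revision_rel", "hit_thrombosis_rel",
                       "hit_mb_rel", "cteph_y1_rel"):
            _check_prob(getattr(self, f_name), f_name)


@dataclass(frozen=True)
class CostSet:
    """Intervention, acute-event and annual state costs (GBP, 2016 prices)."""

    strategy_pharm: Mapping[str, float]
    strategy_mech: Mapping[str, float]
    event: Mapping[str, float]
    state: Mapping[str, float]

    def validate(self) -> None:
        for group_name in ("strategy_pharm", "strategy_mech", "event", "state"):
            for k, v in getattr(self, group_name).items():
                if v < 0:
                    raise ValidationError(f"cost {group_name}[{k}] is negative: {v}")


@dataclass(frozen=True)
class LongTermRiskSet:
    """Post-90-day event risks: PTS/CTEPH onset, severity and mortality."""

    pts_2yr_sympt_prox_dvt: float
    pts_2yr_sympt_dist_dvt: float
    pts_2yr_asympt_prox_dvt: float
    pts_2yr_asympt_dist_dvt: float
    pts_2yr_nonfatal_pe: float
    prop_pts_severe: float
    cteph_2yr_after_pe: float
    cteph_mortality: float

    def validate(self) -> None:
        for f_name in ("pts_2yr_sympt_prox_dvt", "pts_2yr_sympt_dist_dvt",
                       "pts_2yr_asympt_prox_dvt", "pts_2yr_asympt_dist_dvt",
                       "pts_2yr_nonfatal_pe", "prop_pts_severe",
                       "cteph_2yr_after_pe", "cteph_mortality"):
            _check_prob(getattr(self, f_name), f_name)


@dataclass(frozen=True)
class TreeConfig:
    """Sub-tree probabilities, including documented non-paper defaults.

    The HIT outcome split, the HIT amputation probability, the fatal
    major-bleeding probability and the GI share of the combined GI+ICH risk
    are not quantified in the source tables; the defaults here are package
    placeholders, overridable per run.
    """

    return_to_theatre_after_ssb: float = 1.0
    gi_intervention_frac: float = 0.13
    ssi_given_haematoma: float = 0.2577
    surgical_mgmt_given_ssi: float = 0.44
    revision_vs_return_ratio: float = 0.5
    fatal_mb_prob: float = 0.0
    hit_frac_success: float = 0.94
    hit_frac_thrombosis: float = 0.03
    hit_frac_mb: float = 0.02
    hit_frac_death: float = 0.01
    hit_amputation_prob: float = 0.01
    gi_share_of_gi_ich: float = 0.5
    # 17% PE case fatality read as converting the printed *non-fatal* risk:
    # fatal = nonfatal * f/(1-f).  The alternative reading (fatal = risk/6
    # of all PE) is selected with pe_fatality_mode="of_all".
    pe_fatality_mode: str = "of_nonfatal"

    def validate(self) -> None:
        hit_sum = (self.hit_frac_success + self.hit_frac_thrombosis +
                   self.hit_frac_mb + self.hit_frac_death)
        if abs(hit_sum - 1.0) > 1e-9:
            raise ValidationError(f"HIT outcome split sums to {hit_sum}, not 1")
        if self.hit_amputation_prob > self.hit_frac_success:
            raise ValidationError("hit_amputation_prob exceeds the HIT success mass")
        if self.pe_fatality_mode not in ("of_nonfatal", "of_all"):
            raise ValidationError(f"unknown pe_fatality_mode {self.pe_fatality_mode!r}")


@dataclass(frozen=True)
class MarkovConfig:
    """Markov-phase structural settings (non-paper defaults flagged)."""

    cteph_frac_operable: float = 1.0 / 3.0
    cteph_frac_inoperable: float = 1.0 / 3.0
    cteph_frac_recurrent: float = 1.0 / 3.0
    stroke_dependent_frac: float = 0.25
    half_cycle_correction: bool = False
    annual_utility_decrement: float = 0.0

    def validate(self) -> None:
        s = self.cteph_frac_operable + self.cteph_frac_inoperable + self.cteph_frac_recurrent
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(f"CTEPH stratum weights sum to {s}, not 1")
        _check_prob(self.stroke_dependent_frac, "stroke_dependent_frac")


@dataclass(frozen=True)
class EconSettings:
    threshold_lambda: float = 20_000.0
    discount_rate: float = 0.035
    time_horizon_years: Optional[float] = None  # None = lifetime
    cycle_length_years: float = 1.0
    price_year: int = 2016
    psa_iterations: int = 10_000

    def validate(self) -> None:
        if self.threshold_lambda <= 0:
            raise ValidationError("threshold_lambda must be > 0")
        if not (0.0 <= self.discount_rate < 1.0):
            raise ValidationError("discount_rate must lie in [0, 1)")
        if self.cycle_length_years <= 0:
            raise ValidationError("cycle_length_years must be > 0")


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual all-cause death probabilities q(x)."""

    ages: np.ndarray
    qx: np.ndarray

    def validate(self) -> None:
        if len(self.ages) != len(self.qx) or len(self.ages) == 0:
            raise ValidationError("life table ages and qx must be equal-length, non-empty")
        if np.any(self.qx < 0) or np.any(self.qx > 1):
            raise ValidationError("life table qx outside [0, 1]")
        if self.qx[-1] != 1.0:
            raise ValidationError("life table must end with qx = 1 at the terminal age")

    def lookup(self, age: float) -> float:
        """Annual death probability at the nearest tabulated integer age."""
        idx = int(np.clip(np.searchsorted(self.ages, round(age)), 0, len(self.ages) - 1))
        return float(self.qx[idx])

    def life_expectancy(self, age: float, convention: str = "midyear") -> float:
        """Life expectancy from ``age`` by direct life-table summation.

        ``convention="midyear"`` credits half a year to those dying within a
        year (matches cohort accrual with half-cycle correction);
        ``"cycle-start"`` credits the full year to anyone alive at its start
        (matches cohort accrual without half-cycle correction).
        """
        if convention not in ("midyear", "cycle-start"):
            raise ValueError(f"unknown convention {convention!r}")
        i0 = int(np.clip(np.searchsorted(self.ages, round(age)), 0, len(self.ages) - 1))
        surv = 1.0
        total = 0.0
        for q in self.qx[i0:]:
            if convention == "midyear":
                total += surv * (1.0 - q) + surv * q * 0.5
            else:
                total += surv
            surv *= 1.0 - q
            if surv < 1e-15:
                break
        return total


@dataclass(frozen=True)
class ModelInputs:
    """Complete parameter set for one population."""

    cohort: CohortSpec
    strategies: Sequence[StrategySpec]
    baseline: BaselineRiskSet
    absolute_risks: Mapping[str, StrategyRisks]
    utilities: UtilitySet
    costs: CostSet
    long_term: LongTermRiskSet
    settings: EconSettings
    life_table: LifeTable
    tree_config: TreeConfig = field(default_factory=TreeConfig)
    markov_config: MarkovConfig = field(default_factory=MarkovConfig)
    comparator: str = COMPARATOR
    #: standard errors by "block.name" key, where a source reports one
    #: (used by the probabilistic analysis to build sampling distributions)
    param_se: Mapping[str, float] = field(default_factory=dict)

    @property
    def strategy_names(self) -> list[str]:
        return [s.name for s in self.strategies]

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"unknown strategy {name!r}")

    def validate(self) -> None:
        self.cohort.validate()
        self.baseline.validate()
        self.utilities.validate()
        self.costs.validate()
        self.long_term.validate()
        self.settings.validate()
        self.life_table.validate()
        self.tree_config.validate()
        self.markov_config.validate()
        names = set(self.strategy_names)
        if len(names) != len(self.strategies):
            raise ValidationError("duplicate strategy names")
        if self.comparator not in names:
            raise ValidationError(f"comparator {self.comparator!r} not in strategy panel")
        for s in self.strategies:
            s.validate()
            if s.name not in self.absolute_risks:
                raise ValidationError(f"no absolute risks for strategy {s.name!r}")
            self.absolute_risks[s.name].validate(s.name)
            for group in (self.costs.strategy_pharm, self.costs.strategy_mech):
                if s.name not in group:
                    raise ValidationError(f"no intervention cost for strategy {s.name!r}")

    def replace(self, **kwargs) -> "ModelInputs":
        return replace(self, **kwargs)
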