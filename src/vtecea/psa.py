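"""Probabilistic sensitivity analysis.

The published analysis ran the model probabilistically without stating
distribution families, so this module's defaults follow standard practice
and are config-overridable: beta for probabilities (moment-matched from
mean/SE, with SE taken from printed values, from 95% interval widths, or
defaulting to a configurable fraction of the mean), gamma for event and
state costs (SE 20% of the mean by default; intervention unit prices stay
fixed), and lognormal for relative treatment effects with the log-scale SD
matched to the printed credible intervals.  Where a strategy's DVT or PE
effect was imputed from the other by proportionality, one standard-normal
draw drives both (perfect correlation).  Structural fractions (proximal
splits, sub-tree branching) are fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cea import rank_by_nmb
from .pipeline import totals_for_strategies
from .types import EventRisk, ModelInputs, StrategyRisks, ValidationError


@dataclass(frozen=True)
class PSAConfig:
    default_se_frac: float = 0.2     # SE as fraction of mean when unprinted
    cost_se_frac: float = 0.2
    bleeding_log_sd: float = 0.2     # log-OR sd for bleeding effects (no CrIs printed)
    effect_log_sd_fallback: float = 0.5
    all_fixed: bool = False          # degenerate draws (diagnostics)


@dataclass(frozen=True)
class DistributionSpec:
    """One sampled parameter: its path, family and hyperparameters."""

    path: str
    family: str                      # beta | gamma | lognormal | fixed
    params: dict


def beta_moments(mean: float, se: float, path: str = "") -> tuple[float, float]:
    """Method-of-moments beta hyperparameters; errors if infeasible."""
    if not (0.0 < mean < 1.0):
        raise ValidationError(f"{path}: beta mean must lie in (0,1), got {mean}")
    if se <= 0:
        raise ValidationError(f"{path}: beta SE must be > 0")
    nu = mean * (1.0 - mean) / se**2 - 1.0
    if nu <= 0:
        raise ValidationError(
            f"{path}: infeasible beta moment match (SE {se} too large for mean {mean})"
        )
    return mean * nu, (1.0 - mean) * nu


def gamma_moments(mean: float, se: float, path: str = "") -> tuple[float, float]:
    """(shape, scale) matching the first two moments."""
    if mean <= 0 or se <= 0:
        raise ValidationError(f"{path}: gamma needs positive mean and SE")
    return (mean / se) ** 2, se**2 / mean


def lognormal_sigma_from_ci(point: float, low: Optional[float],
                            high: Optional[float], fallback: float) -> float:
    """Log-scale SD from a 95% interval (half-width/1.96 when one side is 0)."""
    if point <= 0:
        return fallback
    if low is not None and high is not None and low > 0 and high > 0:
        return (math.log(high) - math.log(low)) / (2 * 1.96)
    if high is not None and high > 0:
        return max((math.log(high) - math.log(point)) / 1.96, 1e-6)
    return fallback


def _se_for(mean: float, printed_se: Optional[float],
            low: Optional[float], high: Optional[float], frac: float) -> float:
    if printed_se:
        return printed_se
    if low is not None and high is not None and high > low:
        return (high - low) / (2 * 1.96)
    return max(mean * frac, 1e-12)


def assign_distributions(
    inputs: ModelInputs, config: PSAConfig = PSAConfig()
) -> list[DistributionSpec]:
    """The full set of sampling distributions for one parameter set."""
    specs: list[DistributionSpec] = []
    se = inputs.param_se

    def beta_spec(path, mean, printed_se=None, low=None, high=None):
        if config.all_fixed or mean <= 0.0 or mean >= 1.0:
            specs.append(DistributionSpec(path, "fixed", {"value": mean}))
            return
        s = _se_for(mean, printed_se, low, high, config.default_se_frac)
        a, b = beta_moments(mean, s, path)
        specs.append(DistributionSpec(path, "beta", {"alpha": a, "beta": b}))

    def gamma_spec(path, mean):
        if config.all_fixed or mean <= 0.0:
            specs.append(DistributionSpec(path, "fixed", {"value": mean}))
            return
        shape, scale = gamma_moments(mean, mean * config.cost_se_frac, path)
        specs.append(DistributionSpec(path, "gamma", {"shape": shape, "scale": scale}))

    b = inputs.baseline
    comp = inputs.absolute_risks[inputs.comparator]
    beta_spec("baseline.total_dvt", b.total_dvt,
              low=comp.dvt.low95, high=comp.dvt.high95)
    beta_spec("baseline.nonfatal_pe", b.nonfatal_pe,
              low=comp.pe.low95, high=comp.pe.high95)
    for name in ("pe_case_fatality", "mb_surgical_site", "mb_gi_ich", "mb_other",
                 "crnmb", "wound_haematoma_frac_of_crnmb", "hit"):
        beta_spec(f"baseline.{name}", getattr(b, name),
                  printed_se=se.get(f"baseline.{name}"))
    beta_spec("other.ssi_given_haematoma", inputs.tree_config.ssi_given_haematoma,
              printed_se=se.get("other.ssi_given_haematoma"))
    beta_spec("other.surgical_mgmt_given_ssi", inputs.tree_config.surgical_mgmt_given_ssi,
              printed_se=se.get("other.surgical_mgmt_given_ssi"))

    lt = inputs.long_term
    for name in ("pts_2yr_sympt_prox_dvt", "pts_2yr_sympt_dist_dvt",
                 "pts_2yr_asympt_prox_dvt", "pts_2yr_asympt_dist_dvt",
                 "pts_2yr_nonfatal_pe", "prop_pts_severe", "cteph_mortality"):
        beta_spec(f"long_term.{name}", getattr(lt, name))
    # CrI printed for the 2-year CTEPH incidence
    cr = None
    beta_spec("long_term.cteph_2yr_after_pe", lt.cteph_2yr_after_pe,
              printed_se=se.get("long_term.cteph_2yr_after_pe"), low=cr, high=cr)

    u = inputs.utilities
    beta_spec("utility.preop", u.preop)
    beta_spec("utility.post_9mo", u.post_9mo, printed_se=u.post_9mo_se)
    for name in ("sympt_prox_dvt_rel", "sympt_dist_dvt_rel", "nonfatal_pe_rel",
                 "mb_rel", "ich_stroke_rel", "ssi_rel", "post_infected_revision_rel",
                 "hit_thrombosis_rel", "hit_mb_rel", "post_stroke_rel",
                 "cteph_y1_rel", "crnmb_abs", "pts_mildmod_abs", "pts_severe_abs",
                 "warfarin_treated_abs", "hit_abs", "post_amputation_abs"):
        beta_spec(f"utility.{name}", getattr(u, name))

    for name, value in inputs.costs.event.items():
        gamma_spec(f"cost_event.{name}", value)
    for name, value in inputs.costs.state.items():
        gamma_spec(f"cost_state.{name}", value)

    # relative treatment effects (lognormal): DVT/PE as risk ratios vs the
    # baseline, bleeding/CRNMB as odds ratios vs the comparator's table row
    fb = config.effect_log_sd_fallback
    for strategy in inputs.strategy_names:
        if strategy == inputs.comparator:
            continue
        r = inputs.absolute_risks[strategy]
        for event, base_value in (("dvt", b.total_dvt), ("pe", b.nonfatal_pe)):
            er: EventRisk = getattr(r, event)
            point_rr = er.value / base_value if base_value > 0 else 1.0
            if er.low95 is None and er.high95 is None:
                sigma = None  # imputed by proportionality: partner's draw
            else:
                sigma = lognormal_sigma_from_ci(
                    er.value, er.low95, er.high95, fb)
            family = "fixed" if config.all_fixed else "lognormal"
            params = ({"value": point_rr} if config.all_fixed
                      else {"point": point_rr, "sigma": sigma})
            specs.append(DistributionSpec(f"effect.{strategy}.{event}", family, params))
        for event in ("gi_ich", "ssb", "other_mb", "crnmb"):
            p_s = getattr(r, event).value
            p_c = getattr(comp, event).value
            point_or = ((p_s / (1 - p_s)) / (p_c / (1 - p_c))
                        if 0 < p_s < 1 and 0 < p_c < 1 else 1.0)
            if config.all_fixed:
                specs.append(DistributionSpec(
                    f"bleed_or.{strategy}.{event}", "fixed", {"value": point_or}))
            else:
                specs.append(DistributionSpec(
                    f"bleed_or.{strategy}.{event}", "lognormal",
                    {"point": point_or, "sigma": config.bleeding_log_sd}))
    return specs


# ---------------------------------------------------------------------------
# sampling machinery


class ParameterSampler:
    """Pre-draws all parameter values for n iterations (vectorized), then
    materializes perturbed ModelInputs per iteration."""

    def __init__(self, inputs: ModelInputs, config: PSAConfig = PSAConfig()):
        self.inputs = inputs
        self.config = config
        self.specs = assign_distributions(inputs, config)
        self.n_capped = 0

    def draw_all(self, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
        draws: dict[str, np.ndarray] = {}
        # shared normals per strategy for proportionality-correlated effects
        z_shared = {
            s: rng.standard_normal(n) for s in self.inputs.strategy_names
        }
        for spec in self.specs:
            if spec.family == "fixed":
                draws[spec.path] = np.full(n, spec.params["value"])
            elif spec.family == "beta":
                draws[spec.path] = rng.beta(spec.params["alpha"], spec.params["beta"], n)
            elif spec.family == "gamma":
                draws[spec.path] = rng.gamma(spec.params["shape"], spec.params["scale"], n)
            elif spec.family == "lognormal":
                point, sigma = spec.params["point"], spec.params["sigma"]
                if spec.path.startswith("effect."):
                    _, strategy, _ = spec.path.split(".")
                    z = z_shared[strategy]
                    if sigma is None:
                        # proportionality: reuse the partner's sigma
                        sigma = self._partner_sigma(spec.path)
                else:
                    z = rng.standard_normal(n)
                draws[spec.path] = point * np.exp(sigma * z)
            else:
                raise ValidationError(f"unknown family {spec.family!r}")
        return draws

    def _partner_sigma(self, path: str) -> float:
        _, strategy, event = path.split(".")
        partner = "pe" if event == "dvt" else "dvt"
        for spec in self.specs:
            if spec.path == f"effect.{strategy}.{partner}":
                sigma = spec.params.get("sigma")
                return sigma if sigma is not None else self.config.effect_log_sd_fallback
        return self.config.effect_log_sd_fallback

    def materialize(self, draws: dict[str, np.ndarray], i: int) -> ModelInputs:
        """Perturbed ModelInputs for iteration i."""
        base = self.inputs
        if self.config.all_fixed:
            # degenerate draws equal the point values: the inputs ARE the base
            # inputs, bit-for-bit (no round-trips through derived quantities)
            return base

        def get(path, default):
            arr = draws.get(path)
            return float(arr[i]) if arr is not None else default

        b = base.baseline
        baseline = replace(
            b,
            total_dvt=get("baseline.total_dvt", b.total_dvt),
            symptomatic_dvt=get("baseline.total_dvt", b.total_dvt)
            * (b.symptomatic_dvt / b.total_dvt),
            nonfatal_pe=get("baseline.nonfatal_pe", b.nonfatal_pe),
            pe_case_fatality=get("baseline.pe_case_fatality", b.pe_case_fatality),
            mb_surgical_site=get("baseline.mb_surgical_site", b.mb_surgical_site),
            mb_gi_ich=get("baseline.mb_gi_ich", b.mb_gi_ich),
            mb_other=get("baseline.mb_other", b.mb_other),
            crnmb=get("baseline.crnmb", b.crnmb),
            wound_haematoma_frac_of_crnmb=get(
                "baseline.wound_haematoma_frac_of_crnmb",
                b.wound_haematoma_frac_of_crnmb),
            hit=get("baseline.hit", b.hit),
        )
        tree_config = replace(
            base.tree_config,
            ssi_given_haematoma=get("other.ssi_given_haematoma",
                                    base.tree_config.ssi_given_haematoma),
            surgical_mgmt_given_ssi=get("other.surgical_mgmt_given_ssi",
                                        base.tree_config.surgical_mgmt_given_ssi),
        )
        lt = base.long_term
        long_term = replace(
            lt,
            **{name: get(f"long_term.{name}", getattr(lt, name))
               for name in ("pts_2yr_sympt_prox_dvt", "pts_2yr_sympt_dist_dvt",
                            "pts_2yr_asympt_prox_dvt", "pts_2yr_asympt_dist_dvt",
                            "pts_2yr_nonfatal_pe", "prop_pts_severe",
                            "cteph_2yr_after_pe", "cteph_mortality")},
        )
        u = base.utilities
        utilities = replace(
            u,
            preop=min(get("utility.preop", u.preop), get("utility.post_9mo", u.post_9mo)),
            post_9mo=get("utility.post_9mo", u.post_9mo),
            **{name: get(f"utility.{name}", getattr(u, name))
               for name in ("sympt_prox_dvt_rel", "sympt_dist_dvt_rel",
                            "nonfatal_pe_rel", "mb_rel", "ich_stroke_rel",
                            "ssi_rel", "post_infected_revision_rel",
                            "hit_thrombosis_rel", "hit_mb_rel", "post_stroke_rel",
                            "cteph_y1_rel", "crnmb_abs", "pts_mildmod_abs",
                            "pts_severe_abs", "warfarin_treated_abs", "hit_abs",
                            "post_amputation_abs")},
        )
        costs = replace(
            base.costs,
            event={k: get(f"cost_event.{k}", v) for k, v in base.costs.event.items()},
            state={k: get(f"cost_state.{k}", v) for k, v in base.costs.state.items()},
        )

        capped = False
        absolute_risks = {}
        comp = base.absolute_risks[base.comparator]
        for strategy in base.strategy_names:
            r = base.absolute_risks[strategy]
            if strategy == base.comparator:
                absolute_risks[strategy] = r
                continue
            vals = {}
            for event, base_value in (("dvt", baseline.total_dvt),
                                      ("pe", baseline.nonfatal_pe)):
                rr = get(f"effect.{strategy}.{event}", None)
                if rr is None:
                    vals[event] = getattr(r, event)
                    continue
                p = base_value * rr
                if p > 1.0:
                    p, capped = 1.0, True
                vals[event] = EventRisk(p)
            # the tree needs DVT + all-PE (incl. the fatal conversion) <= 1;
            # cap extreme joint draws proportionally and flag the iteration
            f = baseline.pe_case_fatality
            pe_scale = 1.0 / (1.0 - f) if base.tree_config.pe_fatality_mode == "of_nonfatal" else 1.0
            vte_total = vals["dvt"].value + vals["pe"].value * pe_scale
            if vte_total > 1.0:
                shrink = 1.0 / vte_total
                vals["dvt"] = EventRisk(vals["dvt"].value * shrink)
                vals["pe"] = EventRisk(vals["pe"].value * shrink)
                capped = True
            for event, base_attr in (("gi_ich", "mb_gi_ich"),
                                     ("ssb", "mb_surgical_site"),
                                     ("other_mb", "mb_other"), ("crnmb", "crnmb")):
                orv = get(f"bleed_or.{strategy}.{event}", None)
                p_c = getattr(comp, event).value
                if orv is None or not (0 < p_c < 1):
                    vals[event] = getattr(r, event)
                    continue
                odds = orv * p_c / (1 - p_c)
                vals[event] = EventRisk(odds / (1 + odds))
            mb_total = vals["gi_ich"].value + vals["ssb"].value + vals["other_mb"].value
            if mb_total > 1.0:
                shrink = 1.0 / mb_total
                for event in ("gi_ich", "ssb", "other_mb"):
                    vals[event] = EventRisk(vals[event].value * shrink)
                capped = True
            absolute_risks[strategy] = StrategyRisks(
                proportionality_flag=r.proportionality_flag, **vals)
        if capped:
            self.n_capped += 1

        return base.replace(
            baseline=baseline, tree_config=tree_config, long_term=long_term,
            utilities=utilities, costs=costs, absolute_risks=absolute_risks,
        )


# ---------------------------------------------------------------------------
# running and summarizing


@dataclass
class PSASummary:
    strategies: list[str]
    comparator: str
    lam: float
    qalys: np.ndarray            # (n_iter, n_strategies)
    costs: np.ndarray
    summary: pd.DataFrame
    ceac_curve: pd.DataFrame     # index lambda, columns strategies
    prob_most_ce: pd.Series
    n_capped_iterations: int = 0

    def scatter(self) -> pd.DataFrame:
        """Iteration-level incremental (cost, QALYs) vs the comparator."""
        j = self.strategies.index(self.comparator)
        rows = []
        for s_idx, name in enumerate(self.strategies):
            rows.append(pd.DataFrame({
                "iteration": np.arange(len(self.qalys)),
                "strategy": name,
                "inc_cost": self.costs[:, s_idx] - self.costs[:, j],
                "inc_qalys": self.qalys[:, s_idx] - self.qalys[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


def ceac(qalys: np.ndarray, costs: np.ndarray,
         lambdas: Sequence[float], strategies: Sequence[str]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves: P(max NMB) per threshold."""
    if len(qalys) == 0:
        raise ValueError("need at least one iteration")
    out = {}
    for lam in lambdas:
        nmb = qalys * lam - costs
        winners = np.argmax(nmb, axis=1)
        out[lam] = np.bincount(winners, minlength=qalys.shape[1]) / len(qalys)
    return pd.DataFrame.from_dict(out, orient="index", columns=list(strategies)).rename_axis("lambda")


def run_psa(
    inputs: ModelInputs,
    n_iter: Optional[int] = None,
    seed: int = 0,
    config: PSAConfig = PSAConfig(),
    lambda_grid: Optional[Sequence[float]] = None,
) -> PSASummary:
    """Draw parameter sets, re-run the full model per draw, and summarize.

    Reproducible given ``seed``.  Probabilities produced above 1 by extreme
    relative-effect draws are capped and the iteration counted.
    """
    if n_iter is None:
        n_iter = inputs.settings.psa_iterations
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    lam = inputs.settings.threshold_lambda
    if lambda_grid is None:
        lambda_grid = list(range(0, 50_001, 2_500))

    rng = np.random.default_rng(seed)
    sampler = ParameterSampler(inputs, config)
    draws = sampler.draw_all(rng, n_iter)
    names = inputs.strategy_names
    qalys = np.empty((n_iter, len(names)))
    costs = np.empty((n_iter, len(names)))
    for i in range(n_iter):
        per_iter = sampler.materialize(draws, i)
        qalys[i], costs[i] = totals_for_strategies(per_iter)

    nmbs = qalys * lam - costs
    j = names.index(inputs.comparator)
    inmb = nmbs - nmbs[:, [j]]
    winners = np.argmax(nmbs, axis=1)
    prob_ce = pd.Series(
        np.bincount(winners, minlength=len(names)) / n_iter, index=names)
    ranks = np.empty_like(qalys, dtype=int)
    for i in range(n_iter):
        ranks[i] = rank_by_nmb(qalys[i], costs[i], lam, names)

    pct = lambda a, q: np.percentile(a, q, axis=0)
    summary = pd.DataFrame({
        "mean_qalys": qalys.mean(axis=0),
        "qalys_lo": pct(qalys, 2.5), "qalys_hi": pct(qalys, 97.5),
        "mean_cost": costs.mean(axis=0),
        "cost_lo": pct(costs, 2.5), "cost_hi": pct(costs, 97.5),
        "mean_inmb": inmb.mean(axis=0),
        "inmb_lo": pct(inmb, 2.5), "inmb_hi": pct(inmb, 97.5),
        "prob_most_ce": prob_ce.to_numpy(),
        "mean_rank": ranks.mean(axis=0),
        "rank_lo": pct(ranks, 2.5), "rank_hi": pct(ranks, 97.5),
    }, index=pd.Index(names, name="strategy"))
    summary["rank_by_mean_nmb"] = rank_by_nmb(
        qalys.mean(axis=0), costs.mean(axis=0), lam, names)

    curve = ceac(qalys, costs, lambda_grid, names)
    return PSASummary(
        strategies=list(names), comparator=inputs.comparator, lam=lam,
        qalys=qalys, costs=costs, summary=summary, ceac_curve=curve,
        prob_most_ce=prob_ce, n_capped_iterations=sampler.n_capped,
    )
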