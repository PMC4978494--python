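"""Incremental cost-effectiveness analysis and uncertainty propagation.

Deterministic incremental results (:func:`icer`, :func:`pool`), probabilistic
sensitivity analysis (:func:`run_psa`) with cost-effectiveness acceptability
curves (:func:`ceac`), paired ratio estimates between strata
(:func:`ratio_with_ci`), one-way tornado analysis (:func:`tornado`), and
declarative scenario overrides (:data:`SCENARIOS`, :func:`run_scenarios`).

All of these operate on a *pipeline closure*: a callable mapping a
:class:`ModelParameters` bundle to an incremental (QALY, cost) pair, supplied
by the model layer.  That keeps the uncertainty machinery independent of how
the cohorts are actually simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .outcomes import CostSet, DisabilityWeights, PyldSchedule
from .survival import AGE_BANDS, TreatmentEffect

__all__ = [
    "EconResult",
    "ModelParameters",
    "PsaSpec",
    "icer",
    "pool",
    "run_psa",
    "ceac",
    "ratio_with_ci",
    "tornado",
    "SCENARIOS",
    "run_scenarios",
]

Pipeline = Callable[["ModelParameters"], tuple[float, float]]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class ModelParameters:
    """Everything the cohort pipeline needs beyond the mortality inputs."""

    dw: DisabilityWeights = field(default_factory=DisabilityWeights)
    costs: CostSet = field(default_factory=CostSet)
    effect: TreatmentEffect = field(default_factory=TreatmentEffect)
    chf_rate: float = 0.01
    discount_rate: float = 0.03
    cure_year: int = 20
    #: replace the pYLD schedule with zero (life-years-gained scenario)
    zero_pyld: bool = False
    #: per-subtype treatment-effect override (treatment-effect heterogeneity
    #: scenario); falls back to ``effect`` for subtypes not listed
    effect_by_subtype: Mapping[str, TreatmentEffect] | None = None

    def effect_for(self, subtype_name: str) -> TreatmentEffect:
        if self.effect_by_subtype and subtype_name in self.effect_by_subtype:
            return self.effect_by_subtype[subtype_name]
        return self.effect


@dataclass(frozen=True)
class EconResult:
    """Incremental result for one stratum (or a pooled set)."""

    delta_qalys: float
    delta_cost: float
    age_group: str = ""
    subtype: str = ""
    stratum: str = ""

    @property
    def icer(self) -> float | str:
        return icer(self.delta_cost, self.delta_qalys)


def icer(delta_cost: float, delta_qalys: float) -> float | str:
    """Incremental cost-effectiveness ratio, with dominance flags.

    Returns the ratio when the intervention adds QALYs at positive cost (or
    loses both, the steep south-west quadrant); ``"dominant"`` when it adds
    QALYs and saves money; ``"dominated"`` when it loses QALYs at
    non-negative cost; ``"undefined"`` when both increments are zero.
    """
    if delta_qalys == 0 and delta_cost == 0:
        return UNDEFINED
    if delta_qalys > 0:
        return DOMINANT if delta_cost <= 0 else delta_cost / delta_qalys
    if delta_cost >= 0:
        return DOMINATED
    return delta_cost / delta_qalys


def pool(results: Sequence[EconResult], weights: Sequence[float]) -> EconResult:
    """Weight-average increments across strata; the pooled ICER is recomputed
    from the pooled increments, never averaged over stratum ICERs."""
    if len(results) != len(weights):
        raise ValueError("one weight per result required")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    dq = float(np.dot(w, [r.delta_qalys for r in results]))
    dc = float(np.dot(w, [r.delta_cost for r in results]))
    ages = {r.age_group for r in results}
    return EconResult(
        delta_qalys=dq,
        delta_cost=dc,
        age_group=ages.pop() if len(ages) == 1 else "pooled",
        subtype="pooled",
        stratum="pooled",
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PsaSpec:
    """Monte Carlo design: 2,000 draws by default; log-normal treatment RRs
    (per-band SE on the log scale), beta disability weights, gamma costs with
    10% SE, log-normal CHF rate."""

    n_draws: int = 2000
    seed: int = 0
    cost_se_frac: float = 0.10
    chf_se_ln: float = 0.211
    #: draw one shared standard-normal deviate for all age bands instead of
    #: independent per-band draws
    shared_hr_draw: bool = False

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.cost_se_frac < 0 or self.chf_se_ln < 0:
            raise ValueError("standard errors must be non-negative")


_COST_FIELDS = (
    "trastuzumab_drug",
    "administration",
    "travel_accommodation",
    "cardiac_monitoring",
    "chf_bundle",
    "other_cause_death_last6mo",
)
_COST_SCHEDULES = ("diag_treatment", "remission", "preterminal", "terminal", "background")
_DW_FIELDS = ("treatment", "preterminal", "terminal", "remission_initial", "chf")


def _gamma_mult(rng: np.random.Generator, se_frac: float) -> float:
    """Gamma multiplier with mean 1 and the given fractional SE
    (shape = (mean/SE)^2, scale = SE^2/mean)."""
    if se_frac == 0:
        return 1.0
    shape = 1.0 / se_frac**2
    return float(rng.gamma(shape, se_frac**2))


def draw_parameters(
    base: ModelParameters, spec: PsaSpec, rng: np.random.Generator
) -> ModelParameters:
    """One joint draw from the PSA distributions (parameters independent)."""
    # Treatment RRs: log-normal around ln RR with the band's SE(lnRR).
    if spec.shared_hr_draw:
        z = {band: rng.standard_normal() for band in [None]}[None]
        zs = {band: z for band in AGE_BANDS}
    else:
        zs = {band: rng.standard_normal() for band in AGE_BANDS}
    rr = {
        band: min(
            1.0,
            base.effect.rr_bc_by_age[band]
            * float(np.exp(zs[band] * base.effect.se_ln_rr_by_age[band])),
        )
        for band in AGE_BANDS
    }
    effect = TreatmentEffect(
        hr_os=base.effect.hr_os,
        rr_bc_by_age=rr,
        se_ln_rr_by_age=dict(base.effect.se_ln_rr_by_age),
        benefit_duration=base.effect.benefit_duration,
        discontinuation_benefit_fraction=base.effect.discontinuation_benefit_fraction,
        enforce_ordering=False,
    )

    # Disability weights: beta with the published alphas.
    dw_draws = {}
    for name in _DW_FIELDS:
        a1, a2 = base.dw.alphas[name]
        dw_draws[name] = float(rng.beta(a1, a2))
    dw = replace(base.dw, **dw_draws)

    # Costs: independent gamma multipliers per component.
    scalars = {
        name: getattr(base.costs, name) * _gamma_mult(rng, spec.cost_se_frac)
        for name in _COST_FIELDS
    }
    schedules = {
        name: getattr(base.costs, name).scaled(_gamma_mult(rng, spec.cost_se_frac))
        for name in _COST_SCHEDULES
    }
    costs = replace(base.costs, **scalars, **schedules)

    chf_rate = min(
        1.0, base.chf_rate * float(np.exp(rng.standard_normal() * spec.chf_se_ln))
    )
    return replace(base, dw=dw, costs=costs, effect=effect, chf_rate=chf_rate)


def run_psa(
    pipeline: Pipeline, base: ModelParameters, spec: PsaSpec
) -> pd.DataFrame:
    """Propagate parameter uncertainty: ``n_draws`` joint draws through the
    pipeline.  Deterministic given ``spec.seed``.  Returns a DataFrame with
    columns ``delta_qalys`` and ``delta_cost``, one row per draw."""
    rng = np.random.default_rng(spec.seed)
    rows = np.empty((spec.n_draws, 2))
    for i in range(spec.n_draws):
        params = draw_parameters(base, spec, rng)
        rows[i] = pipeline(params)
    return pd.DataFrame(rows, columns=["delta_qalys", "delta_cost"])


def ceac(draws: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: for each willingness-to-pay
    threshold, the fraction of draws with positive net monetary benefit
    (lambda * dQALY - dCost > 0), which handles all quadrants."""
    if len(draws) == 0:
        raise ValueError("draws must be non-empty")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ValueError("willingness-to-pay grid must be non-empty")
    dq = draws["delta_qalys"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    prob = [(lam * dq - dc > 0).mean() for lam in wtp]
    return pd.DataFrame({"wtp": wtp, "prob_cost_effective": prob})


def ratio_with_ci(
    draws_a: pd.DataFrame,
    draws_b: pd.DataFrame,
    statistic: str = "delta_qalys",
    point_a: float | None = None,
    point_b: float | None = None,
) -> dict[str, float]:
    """Ratio of a statistic between two strata with a 95% percentile interval
    from paired PSA draws (draws paired by parameter draw index).

    ``statistic`` is ``"delta_qalys"`` or ``"icer"``.  The point estimate
    comes from the deterministic results when provided, else from the mean of
    the paired ratios.
    """
    if len(draws_a) != len(draws_b):
        raise ValueError("draw sets must be paired (equal length)")
    if statistic == "delta_qalys":
        ra = draws_a["delta_qalys"].to_numpy()
        rb = draws_b["delta_qalys"].to_numpy()
    elif statistic == "icer":
        ra = draws_a["delta_cost"].to_numpy() / draws_a["delta_qalys"].to_numpy()
        rb = draws_b["delta_cost"].to_numpy() / draws_b["delta_qalys"].to_numpy()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    ratios = ra / rb
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    point = (
        point_a / point_b
        if point_a is not None and point_b is not None
        else float(np.mean(ratios))
    )
    return {"ratio": float(point), "ci_low": float(lo), "ci_high": float(hi)}


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity analysis


def _quantile_overrides(
    base: ModelParameters, spec: PsaSpec, q: float
) -> dict[str, ModelParameters]:
    """ModelParameters with each uncertain input, one at a time, set to its
    analytic ``q`` quantile (expected values elsewhere)."""
    z = stats.norm.ppf(q)
    out: dict[str, ModelParameters] = {}

    rr_q = {
        band: min(
            1.0,
            base.effect.rr_bc_by_age[band]
            * float(np.exp(z * base.effect.se_ln_rr_by_age[band])),
        )
        for band in AGE_BANDS
    }
    out["emr_risk_ratio"] = replace(
        base,
        effect=TreatmentEffect(
            hr_os=base.effect.hr_os,
            rr_bc_by_age=rr_q,
            se_ln_rr_by_age=dict(base.effect.se_ln_rr_by_age),
            benefit_duration=base.effect.benefit_duration,
            discontinuation_benefit_fraction=base.effect.discontinuation_benefit_fraction,
            enforce_ordering=False,
        ),
    )

    for name in _DW_FIELDS:
        a1, a2 = base.dw.alphas[name]
        out[f"dw_{name}"] = replace(base, dw=replace(base.dw, **{name: float(stats.beta.ppf(q, a1, a2))}))

    if spec.cost_se_frac > 0:
        shape = 1.0 / spec.cost_se_frac**2
        mult = float(stats.gamma.ppf(q, shape, scale=spec.cost_se_frac**2))
    else:
        mult = 1.0
    for name in _COST_FIELDS:
        out[f"cost_{name}"] = replace(
            base, costs=replace(base.costs, **{name: getattr(base.costs, name) * mult})
        )
    for name in _COST_SCHEDULES:
        out[f"cost_{name}"] = replace(
            base, costs=replace(base.costs, **{name: getattr(base.costs, name).scaled(mult)})
        )

    out["chf_rate"] = replace(
        base, chf_rate=min(1.0, base.chf_rate * float(np.exp(z * spec.chf_se_ln)))
    )
    return out


def tornado(
    pipeline: Pipeline, base: ModelParameters, spec: PsaSpec | None = None
) -> pd.DataFrame:
    """One-way sensitivity analysis: each parameter set in turn to its 2.5th
    and 97.5th percentile (expected values only elsewhere), ICER recomputed.
    Bars sorted widest first."""
    spec = spec or PsaSpec()
    lows = _quantile_overrides(base, spec, 0.025)
    highs = _quantile_overrides(base, spec, 0.975)
    rows = []
    for name in lows:
        dq_l, dc_l = pipeline(lows[name])
        dq_h, dc_h = pipeline(highs[name])
        icer_l = dc_l / dq_l
        icer_h = dc_h / dq_h
        rows.append((name, icer_l, icer_h, abs(icer_h - icer_l)))
    df = pd.DataFrame(rows, columns=["parameter", "icer_low", "icer_high", "width"])
    return df.sort_values("width", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Scenario analyses


def _biosimilar(p: ModelParameters) -> ModelParameters:
    return replace(p, costs=replace(p.costs, trastuzumab_drug=p.costs.trastuzumab_drug * 0.7))


def _benefit_20y(p: ModelParameters) -> ModelParameters:
    return replace(p, effect=replace(p.effect, benefit_duration=20))


def _discontinuation_75(p: ModelParameters) -> ModelParameters:
    return replace(p, effect=replace(p.effect, discontinuation_benefit_fraction=0.75))


def _no_dw_pyld(p: ModelParameters) -> ModelParameters:
    return replace(p, dw=p.dw.zeroed(), zero_pyld=True)


def _no_unrelated_costs(p: ModelParameters) -> ModelParameters:
    return replace(p, costs=replace(p.costs, background=p.costs.background.scaled(0.0)))


#: Declarative scenario overrides on the base parameter set.  The
#: treatment-effect heterogeneity scenario (OS HR 0.49 for the three better
#: prognosis subtypes) needs the model's mortality inputs to re-convert the HR
#: and is therefore assembled in the model layer, not here.
SCENARIOS: dict[str, Callable[[ModelParameters], ModelParameters]] = {
    "base_case": lambda p: p,
    "discount_0pct": lambda p: replace(p, discount_rate=0.0),
    "discount_6pct": lambda p: replace(p, discount_rate=0.06),
    "trastuzumab_cost_minus_30pct": _biosimilar,
    "benefit_duration_20y": _benefit_20y,
    "discontinuation_benefit_75pct": _discontinuation_75,
    "no_dw_no_pyld_life_years": _no_dw_pyld,
    "no_unrelated_offset_costs": _no_unrelated_costs,
}


def run_scenarios(
    pipeline: Pipeline,
    base: ModelParameters,
    scenarios: Mapping[str, Callable[[ModelParameters], ModelParameters]] | None = None,
) -> pd.DataFrame:
    """Evaluate each scenario's declarative override of the base parameters."""
    scenarios = scenarios if scenarios is not None else SCENARIOS
    rows = []
    for name, override in scenarios.items():
        if not callable(override):
            raise ValueError(f"unknown scenario entry {name!r}")
        dq, dc = pipeline(override(base))
        rows.append((name, dq, dc, icer(dc, dq)))
    return pd.DataFrame(rows, columns=["scenario", "delta_qalys", "delta_cost", "icer"])
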