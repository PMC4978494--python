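"""Model / Results objects tying the pipeline together.

:class:`CohortCUA` is the user-facing entry point: construct it from synthetic
or file-sourced inputs, call :meth:`~CohortCUA.fit` to obtain a
:class:`CUAResults` carrying base-case incremental QALYs^DW, incremental costs
and ICERs by 5-year age group and ER/PR subtype (plus pooled), and hang the
probabilistic sensitivity analysis, acceptability curves, tornado and scenario
analyses off the results object.

    >>> model = CohortCUA.from_synthetic()
    >>> res = model.fit(age_groups=["50-54"])
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import econ
from .econ import EconResult, ModelParameters, PsaSpec
from .engine import CohortProfile, CohortTrace, run_cohort
from .outcomes import PyldSchedule, accrue
from .survival import (
    SUBTYPE_NAMES,
    AGE_BANDS,
    EmrCurve,
    LifeTable,
    SubtypeSpec,
    TreatmentEffect,
    convert_os_hr_to_bc_rr,
    validate_subtypes,
)
from .synthetic import Stratum, SyntheticConfig, SyntheticInputs, generate_inputs

__all__ = ["CohortCUA", "CUAResults", "AGE_GROUPS", "age_group_midpoint"]

#: 5-year age groups of treatment initiation, 25-29 through 90-94.
AGE_GROUPS: tuple[str, ...] = tuple(f"{lo}-{lo + 4}" for lo in range(25, 95, 5))

#: Better-prognosis subtypes for the treatment-effect heterogeneity scenario.
BETTER_PROGNOSIS = ("ER+/PR+", "ER+/PR-", "ER-/PR+")


def age_group_midpoint(group: str) -> float:
    lo, hi = group.split("-")
    return (int(lo) + int(hi)) / 2.0


class CohortCUA:
    """Markov cohort cost-utility model of 12-month adjuvant trastuzumab
    versus chemotherapy alone in node-positive HER2+ early breast cancer.

    Parameters
    ----------
    life_table, emr, subtypes, pyld, strata
        Mortality and morbidity inputs; ``subtypes`` must be calibrated
        (``emr_multiplier`` set) and ``emr`` is the overall excess-hazard
        curve the multipliers scale.
    params
        Disability weights, costs, treatment effect, CHF rate and discount
        rate; defaults are the published base-case values.
    """

    def __init__(
        self,
        life_table: LifeTable,
        emr: EmrCurve,
        subtypes: Sequence[SubtypeSpec],
        pyld: PyldSchedule,
        strata: Sequence[Stratum] | None = None,
        params: ModelParameters | None = None,
    ):
        validate_subtypes(subtypes)
        for s in subtypes:
            if s.emr_multiplier is None:
                raise ValueError(f"subtype {s.name} is not calibrated")
        self.life_table = life_table
        self.emr = emr
        self.subtypes = list(subtypes)
        self.pyld = pyld
        self.strata = list(strata) if strata else [Stratum("all", 1.0, 1.0)]
        if abs(sum(st.weight for st in self.strata) - 1.0) > 1e-9:
            raise ValueError("stratum weights must sum to 1")
        self.params = params or ModelParameters()

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_synthetic(
        cls,
        cfg: SyntheticConfig | None = None,
        params: ModelParameters | None = None,
    ) -> "CohortCUA":
        inputs = generate_inputs(cfg)
        costs = inputs.costs
        base = params or ModelParameters()
        return cls(
            life_table=inputs.life_table,
            emr=inputs.emr,
            subtypes=inputs.subtypes,
            pyld=inputs.pyld,
            strata=inputs.strata,
            params=replace(base, costs=costs),
        )

    @classmethod
    def from_inputs(
        cls, inputs: SyntheticInputs, params: ModelParameters | None = None
    ) -> "CohortCUA":
        base = params or ModelParameters()
        return cls(
            life_table=inputs.life_table,
            emr=inputs.emr,
            subtypes=inputs.subtypes,
            pyld=inputs.pyld,
            strata=inputs.strata,
            params=replace(base, costs=inputs.costs),
        )

    # -- core evaluation -----------------------------------------------------

    def _pyld_for(self, params: ModelParameters) -> PyldSchedule:
        return PyldSchedule.zero() if params.zero_pyld else self.pyld

    def _run_arm(
        self,
        age: float,
        subtype: SubtypeSpec,
        stratum: Stratum,
        arm: str,
        params: ModelParameters,
    ) -> tuple[CohortTrace, float, float]:
        profile = CohortProfile(
            age_start=age,
            subtype=subtype,
            arm=arm,
            life_table=self.life_table.scaled(stratum.mortality_scale),
            emr=self.emr,
            effect=params.effect_for(subtype.name),
            chf_rate=params.chf_rate,
            stratum=stratum.name,
            stratum_weight=stratum.weight,
        )
        trace = run_cohort(profile)
        acc = accrue(
            trace,
            params.dw,
            params.costs,
            self._pyld_for(params),
            rate=params.discount_rate,
            cure_year=self.emr.cure_year,
        )
        return trace, acc.qalys, acc.cost

    def _evaluate_cell(
        self, age: float, subtype: SubtypeSpec, stratum: Stratum, params: ModelParameters
    ) -> tuple[float, float]:
        """Incremental (QALY, cost) for one (age, subtype, stratum) cell."""
        _, q_t, c_t = self._run_arm(age, subtype, stratum, "trastuzumab", params)
        _, q_c, c_c = self._run_arm(age, subtype, stratum, "chemo_alone", params)
        return q_t - q_c, c_t - c_c

    def evaluate_subtype(
        self, age_group: str, subtype: SubtypeSpec, params: ModelParameters | None = None
    ) -> EconResult:
        """Stratum-weighted incremental result for one subtype."""
        params = params or self.params
        age = age_group_midpoint(age_group)
        dq = dc = 0.0
        for stratum in self.strata:
            q, c = self._evaluate_cell(age, subtype, stratum, params)
            dq += stratum.weight * q
            dc += stratum.weight * c
        return EconResult(
            delta_qalys=dq, delta_cost=dc, age_group=age_group, subtype=subtype.name
        )

    def pipeline(self, age_group: str):
        """Closure mapping a parameter bundle to the pooled incremental
        (QALY, cost) pair for one age group -- the object the PSA, tornado
        and scenario machinery evaluates."""

        def run(params: ModelParameters) -> tuple[float, float]:
            results = [
                self.evaluate_subtype(age_group, s, params) for s in self.subtypes
            ]
            pooled = econ.pool(results, [s.proportion for s in self.subtypes])
            return pooled.delta_qalys, pooled.delta_cost

        return run

    def fit(self, age_groups: Sequence[str] | None = None) -> "CUAResults":
        """Deterministic base case over the age-group grid."""
        groups = list(age_groups) if age_groups else list(AGE_GROUPS)
        for g in groups:
            if g not in AGE_GROUPS:
                raise ValueError(f"unknown age group {g!r}; choose from {AGE_GROUPS}")
        by_cell: dict[tuple[str, str], EconResult] = {}
        for g in groups:
            subtype_results = [self.evaluate_subtype(g, s) for s in self.subtypes]
            for r in subtype_results:
                by_cell[(g, r.subtype)] = r
            by_cell[(g, "pooled")] = replace(
                econ.pool(subtype_results, [s.proportion for s in self.subtypes]),
                age_group=g,
            )
        return CUAResults(model=self, age_groups=groups, results=by_cell)

    # -- overall survival (validation against trial-reported OS) -------------

    def os_curve(
        self, age_group: str, arm: str, years: int = 20, params: ModelParameters | None = None
    ) -> np.ndarray:
        """Pooled (subtype x stratum) overall survival at years 1..``years``."""
        params = params or self.params
        age = age_group_midpoint(age_group)
        os_ = np.zeros(years)
        for stratum in self.strata:
            for sub in self.subtypes:
                trace, _, _ = self._run_arm(age, sub, stratum, arm, params)
                w = stratum.weight * sub.proportion
                os_ += w * np.array(
                    [trace.survival_at(y) for y in range(1, years + 1)]
                )
        return os_


@dataclass
class CUAResults:
    """Fitted base case, with uncertainty and sensitivity analyses on demand."""

    model: CohortCUA
    age_groups: list[str]
    results: dict[tuple[str, str], EconResult]

    # -- tables ---------------------------------------------------------------

    @property
    def table(self) -> pd.DataFrame:
        """Long-format results: one row per (age group, subtype/pooled)."""
        rows = [
            {
                "age_group": g,
                "subtype": s,
                "delta_qalys": r.delta_qalys,
                "delta_cost": r.delta_cost,
                "icer": r.icer,
            }
            for (g, s), r in self.results.items()
        ]
        return pd.DataFrame(rows)

    def wide_table(self, value: str = "icer") -> pd.DataFrame:
        """Age groups x subtypes (+ pooled) matrix of one output."""
        df = self.table.pivot(index="age_group", columns="subtype", values=value)
        cols = [s for s in SUBTYPE_NAMES if s in df.columns] + ["pooled"]
        return df.loc[self.age_groups, cols]

    def get(self, age_group: str, subtype: str = "pooled") -> EconResult:
        return self.results[(age_group, subtype)]

    def summary(self) -> str:
        """Human-readable results summary (2011 NZD per QALY^DW)."""
        lines = [
            "Cost-utility of 12-mo adjuvant trastuzumab vs chemotherapy alone",
            "Incremental QALYs^DW, costs (2011 NZD) and ICERs by age group and ER/PR subtype",
            "=" * 78,
        ]
        for value, label, fmt in [
            ("delta_qalys", "Incremental QALYs^DW", "{:.2f}"),
            ("delta_cost", "Incremental cost (NZD)", "{:,.0f}"),
            ("icer", "ICER (NZD per QALY^DW)", "{:,.0f}"),
        ]:
            wide = self.wide_table(value)
            lines.append(label)
            lines.append(
                wide.map(lambda v: fmt.format(v) if isinstance(v, float) else str(v))
                .to_string()
            )
            lines.append("-" * 78)
        return "\n".join(lines)

    # -- uncertainty ----------------------------------------------------------

    def run_psa(
        self, age_group: str, spec: PsaSpec | None = None, subtype: str | None = None
    ) -> pd.DataFrame:
        """PSA draws of (delta_qalys, delta_cost) for an age group, pooled
        over subtypes by default or for one subtype.  Using the same spec/seed
        for different subtypes yields paired draw sets."""
        spec = spec or PsaSpec()
        if subtype is None:
            pipe = self.model.pipeline(age_group)
        else:
            sub = self._subtype(subtype)
            pipe = lambda p: (
                lambda r: (r.delta_qalys, r.delta_cost)
            )(self.model.evaluate_subtype(age_group, sub, p))
        return econ.run_psa(pipe, self.model.params, spec)

    def ceac(
        self,
        age_group: str,
        wtp_grid: Sequence[float] | None = None,
        spec: PsaSpec | None = None,
        draws: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        if wtp_grid is None:
            wtp_grid = np.arange(0, 150_001, 5_000)
        if draws is None:
            draws = self.run_psa(age_group, spec)
        return econ.ceac(draws, wtp_grid)

    def subtype_ratio(
        self,
        age_group: str,
        statistic: str = "delta_qalys",
        worst: str = "ER-/PR-",
        best: str = "ER+/PR+",
        spec: PsaSpec | None = None,
    ) -> dict[str, float]:
        """Worst- vs best-prognosis ratio of a statistic with a paired 95%
        percentile interval from PSA draws."""
        spec = spec or PsaSpec()
        draws_w = self.run_psa(age_group, spec, subtype=worst)
        draws_b = self.run_psa(age_group, spec, subtype=best)
        rw, rb = self.get(age_group, worst), self.get(age_group, best)
        if statistic == "delta_qalys":
            pa, pb = rw.delta_qalys, rb.delta_qalys
        else:
            pa, pb = rw.icer, rb.icer
        return econ.ratio_with_ci(draws_w, draws_b, statistic, point_a=pa, point_b=pb)

    def tornado(self, age_group: str, spec: PsaSpec | None = None) -> pd.DataFrame:
        return econ.tornado(self.model.pipeline(age_group), self.model.params, spec)

    def scenarios(self, age_group: str) -> pd.DataFrame:
        """All scenario analyses for one age group (pooled subtypes)."""
        scenarios = dict(econ.SCENARIOS)
        scenarios["hr_os_049_better_subtypes"] = self._hr_scenario_override(age_group)
        return econ.run_scenarios(
            self.model.pipeline(age_group), self.model.params, scenarios
        )

    def _hr_scenario_override(self, age_group: str):
        """Treatment-effect heterogeneity: re-convert an OS HR of 0.49 into a
        breast-cancer RR at this cohort's age (competing background mortality
        on the model's own inputs) and assign it to the three better-prognosis
        subtypes."""
        model = self.model

        def override(p: ModelParameters) -> ModelParameters:
            age = age_group_midpoint(age_group)
            rho = convert_os_hr_to_bc_rr(
                0.49, model.life_table, model.emr, age, horizon=p.effect.benefit_duration
            )
            better_effect = TreatmentEffect(
                hr_os=0.49,
                rr_bc_by_age={band: rho for band in AGE_BANDS},
                se_ln_rr_by_age=dict(p.effect.se_ln_rr_by_age),
                benefit_duration=p.effect.benefit_duration,
                discontinuation_benefit_fraction=p.effect.discontinuation_benefit_fraction,
                enforce_ordering=False,
            )
            return replace(
                p, effect_by_subtype={name: better_effect for name in BETTER_PROGNOSIS}
            )

        return override

    def _subtype(self, name: str) -> SubtypeSpec:
        for s in self.model.subtypes:
            if s.name == name:
                return s
        raise KeyError(f"unknown subtype {name!r}")

    # -- plots (optional matplotlib) ------------------------------------------

    def plot_ceac(self, age_group: str, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        curve = self.ceac(age_group, **kwargs)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["wtp"], curve["prob_cost_effective"])
        ax.set_xlabel("Willingness to pay (2011 NZD per QALY$^{DW}$)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_ylim(0, 1)
        ax.set_title(f"CEAC, pooled subtypes, age {age_group}")
        return ax

    def plot_os(self, age_group: str, years: int = 20, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        yrs = np.arange(1, years + 1)
        for arm, label in [("trastuzumab", "Trastuzumab"), ("chemo_alone", "Chemotherapy alone")]:
            ax.plot(yrs, self.model.os_curve(age_group, arm, years), label=label)
        ax.set_xlabel("Years since model entry")
        ax.set_ylabel("Overall survival")
        ax.legend()
        ax.set_title(f"Model overall survival, age {age_group}")
        return ax
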