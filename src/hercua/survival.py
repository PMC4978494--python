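"""Mortality inputs for the cohort model.

Two hazards drive survival in the model: background (other-cause) mortality
from a life table, and the excess mortality rate (EMR) of a diagnosed breast
cancer cohort -- the hazard analogue of relative survival.  This module builds
and calibrates both:

* :class:`LifeTable` -- annual other-cause mortality hazards by age.
* :class:`EmrCurve` -- annual excess hazard by time since diagnosis, zero from
  the statistical cure point (20 y) onward.
* :func:`calibrate_subtype_emr` -- splits one overall EMR curve into four
  ER/PR-subtype curves via multiplicative hazard scale factors, constrained by
  the subtypes' 5-year relative survival ratios and conservation of the
  proportion-weighted 5-year relative survival.
* :func:`convert_os_hr_to_bc_rr` -- converts an all-cause overall-survival
  hazard ratio from a trial into a breast-cancer-death risk ratio at a given
  age, accounting for competing background mortality (which dilutes the
  all-cause effect of a cause-specific treatment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "LifeTable",
    "EmrCurve",
    "SubtypeSpec",
    "TreatmentEffect",
    "SUBTYPE_NAMES",
    "rate_to_annual_prob",
    "calibrate_subtype_emr",
    "convert_os_hr_to_bc_rr",
    "effective_rr",
]

#: Canonical subtype labels, best to worst prognosis.
SUBTYPE_NAMES = ("ER+/PR+", "ER+/PR-", "ER-/PR+", "ER-/PR-")

#: Age bands keying the treatment effect to age at treatment initiation.
AGE_BANDS = ("<40", "40-49", "50-59", ">=60")


def _band_for_age(age: float) -> str:
    if age < 40:
        return "<40"
    if age < 50:
        return "40-49"
    if age < 60:
        return "50-59"
    return ">=60"


# ---------------------------------------------------------------------------
# Life table


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause background mortality hazards by single year of age.

    ``ages`` must be strictly increasing and contiguous; queries beyond the
    last tabulated age clamp to the final rate.
    """

    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if ages.ndim != 1 or ages.shape != rates.shape or ages.size == 0:
            raise ValueError("ages and rates must be equal-length 1-d arrays")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be contiguous single years")
        if np.any(rates < 0):
            raise ValueError("mortality rates must be non-negative")

    def validate_strict(self, age_lo: int = 25, age_hi: int = 110) -> None:
        """Schema validation for file-sourced tables: coverage and a positive
        terminal rate (an open-ended mortality plateau)."""
        if self.ages[0] > age_lo or self.ages[-1] < age_hi:
            raise ValueError(
                f"life table must cover ages {age_lo}-{age_hi}; "
                f"got {self.ages[0]}-{self.ages[-1]}"
            )
        if self.rates[-1] <= 0:
            raise ValueError("rate at the final tabulated age must be > 0")

    def rate_at(self, age: float) -> float:
        """Hazard for the year of age containing ``age`` (clamped to range)."""
        idx = int(np.floor(age)) - int(self.ages[0])
        idx = min(max(idx, 0), self.ages.size - 1)
        return float(self.rates[idx])

    def scaled(self, factor: float) -> "LifeTable":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return LifeTable(self.ages, self.rates * factor)

    # -- CSV round trip ------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        if list(df.columns) != ["age", "rate"]:
            raise ValueError(f"{path}: expected columns ['age', 'rate'], got {list(df.columns)}")
        lt = cls(df["age"].to_numpy(), df["rate"].to_numpy())
        lt.validate_strict()
        return lt

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "rate": self.rates}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Excess mortality curve


@dataclass(frozen=True)
class EmrCurve:
    """Annual excess (breast-cancer) mortality hazard by year since diagnosis.

    ``values[t]`` is the hazard in year ``t`` (0-based, piecewise constant
    within the year).  From ``cure_year`` on the excess hazard is exactly zero:
    the cohort's mortality reverts to the background population's.
    """

    values: np.ndarray
    cure_year: int = 20

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.cure_year:
            raise ValueError(f"need one excess rate per year 0..{self.cure_year - 1}")
        if np.any(values < 0):
            raise ValueError("excess rates must be non-negative")

    def rate_at(self, years_since_dx: int) -> float:
        """Excess hazard for year ``years_since_dx`` (0 at/after cure)."""
        if years_since_dx < 0:
            raise ValueError("years_since_dx must be >= 0")
        if years_since_dx >= self.cure_year:
            return 0.0
        return float(self.values[years_since_dx])

    def scaled(self, factor: float) -> "EmrCurve":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return EmrCurve(self.values * factor, self.cure_year)

    def cumulative(self, years: int) -> float:
        """Cumulative excess hazard over years 0..years-1."""
        years = min(years, self.cure_year)
        return float(np.sum(self.values[:years]))

    @classmethod
    def from_csv(cls, path: str | Path, cure_year: int = 20) -> "EmrCurve":
        df = pd.read_csv(path)
        if list(df.columns) != ["year", "excess_rate"]:
            raise ValueError(
                f"{path}: expected columns ['year', 'excess_rate'], got {list(df.columns)}"
            )
        if list(df["year"]) != list(range(cure_year)):
            raise ValueError(f"{path}: years must be exactly 0..{cure_year - 1}")
        return cls(df["excess_rate"].to_numpy(), cure_year)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"year": np.arange(self.cure_year), "excess_rate": self.values}
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Subtypes and treatment effect


@dataclass(frozen=True)
class SubtypeSpec:
    """One ER/PR subtype: incidence share, 5-y relative survival ratio, and
    (once calibrated) the multiplicative scale applied to the overall EMR."""

    name: str
    proportion: float
    rs5: float
    emr_multiplier: float | None = None

    def __post_init__(self):
        if not (0 < self.rs5 <= 1):
            raise ValueError(f"{self.name}: rs5 must be in (0, 1]")
        if not (0 <= self.proportion <= 1):
            raise ValueError(f"{self.name}: proportion must be in [0, 1]")
        if self.emr_multiplier is not None and self.emr_multiplier <= 0:
            raise ValueError(f"{self.name}: emr_multiplier must be > 0")


def validate_subtypes(subtypes: Sequence[SubtypeSpec]) -> None:
    total = sum(s.proportion for s in subtypes)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"subtype proportions must sum to 1, got {total}")


@dataclass(frozen=True)
class TreatmentEffect:
    """Trastuzumab treatment effect.

    The trials report an all-cause OS hazard ratio; the model applies
    age-band-specific risk ratios on the *excess* (breast-cancer) hazard,
    derived from that HR under competing mortality.  The effect lasts
    ``benefit_duration`` years; patients who discontinue after congestive
    heart failure retain ``discontinuation_benefit_fraction`` of the hazard
    reduction.
    """

    hr_os: float = 0.63
    rr_bc_by_age: Mapping[str, float] = field(
        default_factory=lambda: {"<40": 0.63, "40-49": 0.62, "50-59": 0.56, ">=60": 0.50}
    )
    se_ln_rr_by_age: Mapping[str, float] = field(
        default_factory=lambda: {"<40": 0.078, "40-49": 0.084, "50-59": 0.106, ">=60": 0.136}
    )
    benefit_duration: int = 8
    discontinuation_benefit_fraction: float = 0.5
    #: Table-like inputs must have RR non-increasing with age band; sampled
    #: (PSA) effects may not, so draws disable the ordering check.
    enforce_ordering: bool = True

    def __post_init__(self):
        if self.benefit_duration <= 0:
            raise ValueError("benefit_duration must be > 0")
        rrs = [self.rr_bc_by_age[b] for b in AGE_BANDS]
        for rr in rrs:
            if not (0 < rr <= 1):
                raise ValueError("each band RR must be in (0, 1]")
        if self.enforce_ordering and np.any(np.diff(rrs) > 1e-12):
            raise ValueError("band RRs must be non-increasing with age band")
        if not (0 <= self.discontinuation_benefit_fraction <= 1):
            raise ValueError("discontinuation_benefit_fraction must be in [0, 1]")

    def rr_for_age(self, age: float) -> float:
        """Base breast-cancer-death RR for a cohort starting treatment at ``age``
        (fixed for the cohort's lifetime)."""
        return float(self.rr_bc_by_age[_band_for_age(age)])

    def se_for_age(self, age: float) -> float:
        return float(self.se_ln_rr_by_age[_band_for_age(age)])


# ---------------------------------------------------------------------------
# Operations


def rate_to_annual_prob(rate: float) -> float:
    """Convert a per-person-year hazard to a one-cycle (annual) probability,
    ``1 - exp(-rate)``."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return float(-np.expm1(-rate))


def effective_rr(base_rr: float, benefit_fraction: float) -> float:
    """Risk ratio retained when only ``benefit_fraction`` of the hazard
    reduction applies (e.g. half benefit after 6-month discontinuation)."""
    if not (0 < base_rr <= 1):
        raise ValueError("base_rr must be in (0, 1]")
    if not (0 <= benefit_fraction <= 1):
        raise ValueError("benefit_fraction must be in [0, 1]")
    return 1.0 - benefit_fraction * (1.0 - base_rr)


def calibrate_subtype_emr(
    overall: EmrCurve, subtypes: Sequence[SubtypeSpec], tol: float = 1e-12
) -> list[SubtypeSpec]:
    """Derive subtype EMR multipliers from 5-y relative survival ratios.

    Each subtype's excess hazard is ``k_s * m_e(t)``, realising the intercept
    adjustment on the log-hazard scale as a multiplicative factor.  The
    multipliers solve two constraints:

    1. ratios of subtype 5-y excess-hazard survivals
       ``S_s(5) = exp(-k_s * H5)`` match the ratios of the given rs5 values;
    2. conservation: ``sum_s p_s * S_s(5) = exp(-H5)``, the overall curve's
       own 5-y relative survival.

    Constraint 1 fixes ``k_s`` up to a common log-hazard offset ``c``
    (``k_s = c/H5 - ln(rs5_s)/H5``); constraint 2 determines ``c`` by
    one-dimensional root finding.
    """
    validate_subtypes(subtypes)
    h5 = overall.cumulative(5)
    if h5 <= 0 or np.any(overall.values[:5] <= 0):
        raise ValueError("overall EMR must be positive over years 0-4")

    p = np.array([s.proportion for s in subtypes])
    rs5 = np.array([s.rs5 for s in subtypes])
    target = np.exp(-h5)

    # k_s(c) = (c - ln rs5_s) / H5; conservation residual as a function of c.
    def residual(c: float) -> float:
        s5 = np.exp(-(c - np.log(rs5)) )  # = exp(-c) * rs5
        return float(np.dot(p, s5) - target)

    # Bracket: residual is strictly decreasing in c.
    lo, hi = -50.0, 50.0
    if residual(lo) < 0 or residual(hi) > 0:
        raise ValueError(
            "infeasible rs5 combination: no common offset satisfies conservation "
            f"(residuals {residual(lo):.3g}, {residual(hi):.3g})"
        )
    c = brentq(residual, lo, hi, xtol=tol, rtol=8.9e-16)

    ks = (c - np.log(rs5)) / h5
    if np.any(ks <= 0):
        raise ValueError(
            "infeasible rs5 combination: calibration yields a non-positive "
            f"multiplier (k = {ks})"
        )
    out = [replace(s, emr_multiplier=float(k)) for s, k in zip(subtypes, ks)]
    # conservation check (spec guarantee: within 1e-8)
    resid = abs(float(np.dot(p, np.exp(-ks * h5))) - target)
    if resid > 1e-8:
        raise RuntimeError(f"calibration failed to conserve relative survival (residual {resid:.3g})")
    return out


def implied_rs5(overall: EmrCurve, multipliers: Sequence[float]) -> np.ndarray:
    """5-y relative survival implied by multipliers on the overall curve
    (inverse of :func:`calibrate_subtype_emr` up to a common scale)."""
    h5 = overall.cumulative(5)
    return np.exp(-np.asarray(multipliers, dtype=float) * h5)


def convert_os_hr_to_bc_rr(
    hr_os: float,
    life_table: LifeTable,
    emr: EmrCurve,
    age_at_start: float,
    horizon: int = 8,
) -> float:
    """Convert an all-cause OS hazard ratio to a breast-cancer-death risk ratio.

    Solves for the excess-hazard scale ``rho`` in the treated arm such that the
    ratio of cumulative all-cause hazards over ``horizon`` years equals
    ``hr_os``::

        sum_t [m_b(a+t) + rho * m_e(t)]  =  hr_os * sum_t [m_b(a+t) + m_e(t)]

    Competing background mortality is untouched by treatment, so it dilutes
    the all-cause effect: ``rho <= hr_os`` always, with equality when the
    background hazard is identically zero over the horizon.
    """
    if not (0 < hr_os <= 1):
        raise ValueError("hr_os must be in (0, 1]")
    if horizon < 1:
        raise ValueError("horizon must be >= 1 year")
    bg = sum(life_table.rate_at(age_at_start + t) for t in range(horizon))
    ex = sum(emr.rate_at(t) for t in range(horizon))
    if ex <= 0:
        raise ValueError("excess hazard is zero over the horizon; rho is undefined")

    def residual(rho: float) -> float:
        return (bg + rho * ex) - hr_os * (bg + ex)

    lo = 1e-9
    if residual(lo) > 0:
        raise ValueError(
            "infeasible: background mortality alone exceeds the target all-cause "
            f"hazard reduction (cumulative background {bg:.4g}, excess {ex:.4g}, "
            f"hr_os {hr_os})"
        )
    rho = brentq(residual, lo, 1.0, xtol=1e-10, rtol=8.9e-16)
    return float(rho)
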