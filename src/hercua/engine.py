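"""Six-state annual-cycle Markov cohort simulation.

One run follows a single (age at treatment initiation, ER/PR subtype, arm)
cohort from model entry (post-diagnosis, start of taxane treatment) until age
110 or extinction.  States: treatment (cycle 1), remission, CHF (congestive
heart failure subcohort, cycle 1 of the trastuzumab arm), the pre-terminal /
terminal dying pathway, death from breast cancer, death from other causes.

Within each 12-month cycle, breast-cancer death (excess hazard, scaled by the
subtype multiplier and the treatment risk ratio during the benefit window) and
other-cause death (life-table hazard at current age) compete as constant
hazards; the cause split is proportional to the hazards.  The excess hazard is
zero from the statistical cure point (20 y after diagnosis) onward.

CHF occurs at 6 months in 1% of trastuzumab-arm survivors, forces
discontinuation (half benefit retained for the remaining benefit window),
carries the CHF disability weight for 6 months, and incurs the CHF cost
bundle once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import (
    EmrCurve,
    LifeTable,
    SubtypeSpec,
    TreatmentEffect,
    effective_rr,
)

__all__ = ["CohortProfile", "CohortTrace", "run_cohort", "dying_pathway_split"]

ARMS = ("trastuzumab", "chemo_alone")

#: Months spent in the pre-terminal and terminal states before breast-cancer
#: death, replacing remission time in the final year of life.
PRETERMINAL_MONTHS = 11
TERMINAL_MONTHS = 1

#: Months of taxane treatment within cycle 1.
TREATMENT_MONTHS = 4

#: CHF onset, months into cycle 1.
CHF_ONSET_MONTHS = 6

MAX_AGE = 110
EXTINCTION = 1e-12


def dying_pathway_split(new_bc_deaths: float) -> tuple[float, float]:
    """Person-years of pre-terminal and terminal state time attributable to a
    fraction of the cohort dying of breast cancer within a cycle (11 months
    pre-terminal + 1 month terminal, replacing remission time)."""
    if not (0 <= new_bc_deaths <= 1):
        raise ValueError("death fraction must be in [0, 1]")
    return (
        new_bc_deaths * PRETERMINAL_MONTHS / 12.0,
        new_bc_deaths * TERMINAL_MONTHS / 12.0,
    )


@dataclass(frozen=True)
class CohortProfile:
    """One simulated cohort: who they are and which hazards apply."""

    age_start: float
    subtype: SubtypeSpec
    arm: str
    life_table: LifeTable
    emr: EmrCurve  # overall curve; scaled by subtype.emr_multiplier internally
    effect: TreatmentEffect
    chf_rate: float = 0.01
    stratum_weight: float = 1.0
    stratum: str = "all"

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        if not (25 <= self.age_start <= 94):
            raise ValueError("age_start must lie within the 25-94 grid")
        if not (0 <= self.chf_rate <= 1):
            raise ValueError("CHF rate must be in [0, 1]")
        if self.subtype.emr_multiplier is None:
            raise ValueError("subtype emr_multiplier must be calibrated before running")

    @property
    def base_rr(self) -> float:
        """Treatment RR on the excess hazard (1 in the comparator arm)."""
        if self.arm == "trastuzumab":
            return self.effect.rr_for_age(self.age_start)
        return 1.0


@dataclass
class CohortTrace:
    """Per-cycle occupancy and event fractions (of the initial cohort).

    Occupancy at cycle ``t`` (1-based): survivors to the end of the cycle sit
    in ``treatment``/``chf`` (cycle 1) or ``remission`` (later cycles); the
    fraction dying of breast cancer during the cycle occupies the combined
    ``preterminal_terminal`` dying pathway; ``dead_bc`` holds breast-cancer
    deaths completed before the cycle and ``dead_other`` all other-cause
    deaths through the cycle.  The six columns sum to 1 every cycle.
    """

    age_start: float
    arm: str
    cycles: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    treatment: np.ndarray = field(default_factory=lambda: np.empty(0))
    chf: np.ndarray = field(default_factory=lambda: np.empty(0))
    remission: np.ndarray = field(default_factory=lambda: np.empty(0))
    preterminal_terminal: np.ndarray = field(default_factory=lambda: np.empty(0))
    dead_bc: np.ndarray = field(default_factory=lambda: np.empty(0))
    dead_other: np.ndarray = field(default_factory=lambda: np.empty(0))
    new_bc_deaths: np.ndarray = field(default_factory=lambda: np.empty(0))
    new_oc_deaths: np.ndarray = field(default_factory=lambda: np.empty(0))
    new_chf: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: CHF-flagged alive fraction at the end of each cycle (subcohort marker,
    #: not a separate occupancy column after cycle 1).
    chf_alive: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_cycles(self) -> int:
        return self.cycles.size

    @property
    def alive(self) -> np.ndarray:
        """Alive fraction at the end of each cycle."""
        return self.treatment + self.chf + self.remission

    def survival_at(self, year: int) -> float:
        """Overall survival at the end of ``year`` (1-based cycle index)."""
        if year < 1:
            return 1.0
        idx = min(year, self.n_cycles) - 1
        return float(self.alive[idx])

    def cumulative_bc_deaths(self) -> float:
        return float(self.new_bc_deaths.sum())

    def person_years(self) -> float:
        """Alive person-time: survivors count a full year, breast-cancer
        deaths a full year (the 11+1-month dying pathway), other-cause deaths
        half a year."""
        return float(
            np.sum(self.alive + self.new_bc_deaths + 0.5 * self.new_oc_deaths)
        )

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycles,
                "treatment": self.treatment,
                "chf": self.chf,
                "remission": self.remission,
                "preterminal_terminal": self.preterminal_terminal,
                "dead_bc": self.dead_bc,
                "dead_other": self.dead_other,
                "new_bc_deaths": self.new_bc_deaths,
                "new_oc_deaths": self.new_oc_deaths,
                "new_chf": self.new_chf,
                "chf_alive": self.chf_alive,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.as_dataframe().to_csv(path, index=False)


def _cycle_hazards(
    profile: CohortProfile, cycle: int, rr: float
) -> tuple[float, float]:
    """(breast-cancer, other-cause) hazards for 1-based ``cycle``."""
    k = profile.subtype.emr_multiplier
    h_bc = rr * k * profile.emr.rate_at(cycle - 1)
    h_oc = profile.life_table.rate_at(profile.age_start + cycle - 1)
    return h_bc, h_oc


def _step(alive: float, h_bc: float, h_oc: float, years: float) -> tuple[float, float, float]:
    """Advance a subcohort ``years`` under constant competing hazards.

    Returns (survivors, bc deaths, oc deaths); the cause-of-death split is
    proportional to the hazards.
    """
    h = h_bc + h_oc
    if h <= 0:
        return alive, 0.0, 0.0
    p_die = -np.expm1(-h * years)
    deaths = alive * p_die
    return alive - deaths, deaths * h_bc / h, deaths * h_oc / h


def run_cohort(profile: CohortProfile, horizon: int | None = None) -> CohortTrace:
    """Run the annual-cycle cohort simulation for one profile.

    ``horizon`` caps the number of cycles; by default the run continues until
    age 110 or the alive fraction falls below extinction (1e-12).
    """
    max_cycles = int(np.ceil(MAX_AGE - profile.age_start))
    if horizon is not None:
        if horizon < 1:
            raise ValueError("horizon must cover at least one cycle")
        max_cycles = min(max_cycles, horizon)
    if max_cycles < 1:
        raise ValueError("age_start leaves no room for a single cycle")

    eff = profile.effect
    rr_full = profile.base_rr
    rr_disc = (
        effective_rr(rr_full, eff.discontinuation_benefit_fraction)
        if profile.arm == "trastuzumab" and rr_full < 1.0
        else rr_full
    )
    chf_rate = profile.chf_rate if profile.arm == "trastuzumab" else 0.0

    rows = []
    alive_main = 1.0  # never-CHF subcohort
    alive_chf = 0.0
    cum_bc = 0.0
    cum_oc = 0.0

    for t in range(1, max_cycles + 1):
        in_benefit = profile.arm == "trastuzumab" and t <= eff.benefit_duration
        rr_main = rr_full if in_benefit else 1.0
        rr_chf = rr_disc if in_benefit else 1.0

        bc = oc = chf_new = 0.0
        if t == 1 and chf_rate > 0:
            # Two half-year steps: CHF arises at 6 months among survivors and
            # the CHF subcohort completes the cycle at reduced benefit.
            h_bc, h_oc = _cycle_hazards(profile, t, rr_main)
            alive_main, d_bc, d_oc = _step(alive_main, h_bc, h_oc, 0.5)
            bc += d_bc
            oc += d_oc
            chf_new = chf_rate * alive_main
            alive_chf = chf_new
            alive_main -= chf_new
            alive_main, d_bc, d_oc = _step(alive_main, h_bc, h_oc, 0.5)
            bc += d_bc
            oc += d_oc
            h_bc_c, h_oc_c = _cycle_hazards(profile, t, rr_chf)
            alive_chf, d_bc, d_oc = _step(alive_chf, h_bc_c, h_oc_c, 0.5)
            bc += d_bc
            oc += d_oc
        else:
            h_bc, h_oc = _cycle_hazards(profile, t, rr_main)
            alive_main, d_bc, d_oc = _step(alive_main, h_bc, h_oc, 1.0)
            bc += d_bc
            oc += d_oc
            if alive_chf > 0:
                h_bc_c, h_oc_c = _cycle_hazards(profile, t, rr_chf)
                alive_chf, d_bc, d_oc = _step(alive_chf, h_bc_c, h_oc_c, 1.0)
                bc += d_bc
                oc += d_oc

        rows.append(
            (
                t,
                alive_main if t == 1 else 0.0,  # treatment occupancy
                alive_chf if t == 1 else 0.0,  # chf occupancy
                (alive_main + alive_chf) if t > 1 else 0.0,  # remission
                bc,  # dying pathway this cycle
                cum_bc,  # completed bc deaths before this cycle
                cum_oc + oc,  # other-cause deaths through this cycle
                bc,
                oc,
                chf_new,
                alive_chf,
            )
        )
        cum_bc += bc
        cum_oc += oc
        if alive_main + alive_chf < EXTINCTION:
            break

    arr = np.array(rows, dtype=float)
    return CohortTrace(
        age_start=profile.age_start,
        arm=profile.arm,
        cycles=arr[:, 0].astype(int),
        treatment=arr[:, 1],
        chf=arr[:, 2],
        remission=arr[:, 3],
        preterminal_terminal=arr[:, 4],
        dead_bc=arr[:, 5],
        dead_other=arr[:, 6],
        new_bc_deaths=arr[:, 7],
        new_oc_deaths=arr[:, 8],
        new_chf=arr[:, 9],
        chf_alive=arr[:, 10],
    )
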