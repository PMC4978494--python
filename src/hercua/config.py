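"""Run configuration: schema, validation, loading.

A run is described by one YAML file.  Every model parameter defaults to the
published base-case value, so an empty configuration reproduces the base case
on synthetic inputs; unknown keys are rejected outright.  Mortality inputs
come either from the synthetic generator (``inputs.mode: synthetic``) or from
CSV files with the same schemas the generator writes (``inputs.mode: files``).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .econ import ModelParameters, PsaSpec
from .outcomes import CostSet, DisabilityWeights, PyldSchedule
from .survival import (
    SUBTYPE_NAMES,
    EmrCurve,
    LifeTable,
    SubtypeSpec,
    TreatmentEffect,
    calibrate_subtype_emr,
)
from .synthetic import Stratum, SyntheticConfig, SyntheticInputs, gen_cost_profiles

__all__ = ["RunConfig", "load_config", "build_inputs", "build_parameters", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EffectConfig(_Strict):
    hr_os: float = 0.63
    rr_bc_by_age: dict[str, float] = Field(
        default_factory=lambda: {"<40": 0.63, "40-49": 0.62, "50-59": 0.56, ">=60": 0.50}
    )
    se_ln_rr_by_age: dict[str, float] = Field(
        default_factory=lambda: {"<40": 0.078, "40-49": 0.084, "50-59": 0.106, ">=60": 0.136}
    )
    benefit_duration: int = 8
    discontinuation_benefit_fraction: float = 0.5


class DwConfig(_Strict):
    treatment: float = 0.194
    preterminal: float = 0.513
    terminal: float = 0.521
    remission_initial: float = 0.174
    remission_annual_decay: float = 0.20
    chf: float = 0.088
    chf_duration_months: int = 6


class CostConfig(_Strict):
    trastuzumab_drug: float = 67_812.50
    administration: float = 5_925.96
    travel_accommodation: float = 214.68
    cardiac_monitoring: float = 800.00
    chf_bundle: float = 3_352.78

    @field_validator("*")
    @classmethod
    def non_negative(cls, v):
        if v < 0:
            raise ValueError("costs must be non-negative")
        return v


class SubtypeConfig(_Strict):
    name: str
    proportion: float
    rs5: float


class StratumConfig(_Strict):
    name: str
    weight: float
    mortality_scale: float = 1.0


class InputsConfig(_Strict):
    mode: str = "synthetic"  # "synthetic" | "files"
    life_table: str | None = None
    emr_curve: str | None = None
    pyld: str | None = None
    synthetic: dict = Field(default_factory=dict)  # SyntheticConfig overrides

    @field_validator("mode")
    @classmethod
    def known_mode(cls, v):
        if v not in ("synthetic", "files"):
            raise ValueError("inputs.mode must be 'synthetic' or 'files'")
        return v


class PsaConfig(_Strict):
    n_draws: int = 2000
    cost_se_frac: float = 0.10
    chf_se_ln: float = 0.211
    shared_hr_draw: bool = False


class RunConfig(_Strict):
    """Full run description; defaults reproduce the base case."""

    seed: int = 0
    outdir: str = "results"
    age_groups: list[str] | None = None  # None -> all 25-29 .. 90-94
    discount_rate: float = 0.03
    chf_rate: float = 0.01
    effect: EffectConfig = Field(default_factory=EffectConfig)
    disability_weights: DwConfig = Field(default_factory=DwConfig)
    costs: CostConfig = Field(default_factory=CostConfig)
    subtypes: list[SubtypeConfig] = Field(
        default_factory=lambda: [
            SubtypeConfig(name=n, proportion=p, rs5=r)
            for n, p, r in zip(SUBTYPE_NAMES, (0.37, 0.15, 0.03, 0.45), (0.88, 0.84, 0.78, 0.73))
        ]
    )
    strata: list[StratumConfig] | None = None  # None -> from synthetic config
    inputs: InputsConfig = Field(default_factory=InputsConfig)
    psa: PsaConfig = Field(default_factory=PsaConfig)
    wtp_grid_max: float = 150_000.0
    wtp_grid_step: float = 5_000.0
    #: display-only 2011 PPP conversion factors (never used in computation)
    ppp_display: dict[str, float] = Field(
        default_factory=lambda: {"USD": 0.67, "EUR": 0.53, "GBP": 0.47}
    )

    @field_validator("discount_rate")
    @classmethod
    def rate_ok(cls, v):
        if v < 0:
            raise ValueError("discount rate must be non-negative")
        return v

    @field_validator("chf_rate")
    @classmethod
    def chf_ok(cls, v):
        if not (0 <= v <= 1):
            raise ValueError("CHF rate must be in [0, 1]")
        return v


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults if no path)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        cfg.model_dump_json().encode()
    ).hexdigest()


def build_parameters(cfg: RunConfig, costs: CostSet) -> ModelParameters:
    effect = TreatmentEffect(**cfg.effect.model_dump())
    dw = DisabilityWeights(**cfg.disability_weights.model_dump())
    costs = CostSet(
        **cfg.costs.model_dump(),
        diag_treatment=costs.diag_treatment,
        remission=costs.remission,
        preterminal=costs.preterminal,
        terminal=costs.terminal,
        background=costs.background,
        other_cause_death_last6mo=costs.other_cause_death_last6mo,
    )
    return ModelParameters(
        dw=dw,
        costs=costs,
        effect=effect,
        chf_rate=cfg.chf_rate,
        discount_rate=cfg.discount_rate,
    )


def build_inputs(cfg: RunConfig) -> tuple[SyntheticInputs, ModelParameters]:
    """Materialise mortality/cost/morbidity inputs and the parameter bundle."""
    syn_overrides = dict(cfg.inputs.synthetic)
    syn_overrides.setdefault(
        "subtype_proportions", tuple(s.proportion for s in cfg.subtypes)
    )
    syn_overrides.setdefault("subtype_rs5", tuple(s.rs5 for s in cfg.subtypes))
    syn_cfg = SyntheticConfig(**syn_overrides, seed=cfg.seed)
    if cfg.inputs.mode == "synthetic":
        from .synthetic import generate_inputs

        inputs = generate_inputs(syn_cfg)
    else:
        for field_name in ("life_table", "emr_curve", "pyld"):
            p = getattr(cfg.inputs, field_name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(
                    f"inputs.{field_name}: file not found: {p!r} (mode 'files' "
                    "requires life_table, emr_curve and pyld paths)"
                )
        life_table = LifeTable.from_csv(cfg.inputs.life_table)
        emr = EmrCurve.from_csv(cfg.inputs.emr_curve)
        pyld = PyldSchedule.from_csv(cfg.inputs.pyld)
        raw = [SubtypeSpec(s.name, s.proportion, s.rs5) for s in cfg.subtypes]
        subtypes = calibrate_subtype_emr(emr, raw)
        inputs = SyntheticInputs(
            life_table=life_table,
            emr=emr,
            subtypes=subtypes,
            costs=gen_cost_profiles(syn_cfg),
            pyld=pyld,
            strata=[Stratum(s.name, s.weight, s.mortality_scale) for s in (cfg.strata or [])]
            or [Stratum("all", 1.0, 1.0)],
            config=syn_cfg,
        )
    if cfg.inputs.mode == "synthetic" and cfg.strata is not None:
        inputs = SyntheticInputs(
            life_table=inputs.life_table,
            emr=inputs.emr,
            subtypes=inputs.subtypes,
            costs=inputs.costs,
            pyld=inputs.pyld,
            strata=[Stratum(s.name, s.weight, s.mortality_scale) for s in cfg.strata],
            config=inputs.config,
        )
    params = build_parameters(cfg, inputs.costs)
    return inputs, params


def psa_spec(cfg: RunConfig) -> PsaSpec:
    return PsaSpec(
        n_draws=cfg.psa.n_draws,
        seed=cfg.seed,
        cost_se_frac=cfg.psa.cost_se_frac,
        chf_se_ln=cfg.psa.chf_se_ln,
        shared_hr_draw=cfg.psa.shared_hr_draw,
    )


def wtp_grid(cfg: RunConfig) -> np.ndarray:
    return np.arange(0.0, cfg.wtp_grid_max + cfg.wtp_grid_step / 2, cfg.wtp_grid_step)
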