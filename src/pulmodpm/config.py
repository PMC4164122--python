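"""Scenario configuration: schema, validation, presets, serialization.

A scenario is a declarative YAML/JSON document (``schema_version: 1``)
describing species and body mass, an environment timeline (inspired gas
fractions, barometric pressure, optional isocapnic clamping), a workload
timeline (watts, or treadmill speed/grade, or the incremental treadmill
ramp protocol), a damage pattern, and optional parameter blocks for the
controller, fatigue model, blood chemistry and solver.  Unknown keys are
rejected.  Presets are ordinary config files shipped under
``resources/presets``.
"""

from __future__ import annotations

import hashlib
import json
import os
from importlib import resources as _ilres
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import anatomy, control as ctl
from .blood import BloodChemistry
from .constants import FIO2_AIR, P_BAROMETRIC
from .damage import K_W_DEFAULT, DamageState, damage_from_weight_change, weight_gain_pattern
from .errors import ConfigError

__all__ = ["ScenarioConfig", "load_config", "list_presets", "preset_path"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnvironmentPhase(_Block):
    t: float = 0.0
    fio2: float = FIO2_AIR
    fico2: float = 0.0
    pb: float = Field(default=P_BAROMETRIC, gt=0)
    isocapnic: bool = False

    @model_validator(mode="after")
    def _gas_fractions(self):
        if not (0.0 < self.fio2 <= 1.0):
            raise ValueError(f"fio2 must be in (0, 1], got {self.fio2}")
        if not (0.0 <= self.fico2 <= 1.0):
            raise ValueError(f"fico2 must be in [0, 1], got {self.fico2}")
        if self.fio2 + self.fico2 > 1.0:
            raise ValueError("fio2 + fico2 must not exceed 1")
        return self


class WorkPhase(_Block):
    t: float = 0.0
    watts: float | None = Field(default=None, ge=0)
    speed_m_s: float | None = Field(default=None, ge=0)
    grade_pct: float | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _one_of(self):
        if self.watts is None and self.speed_m_s is None:
            raise ValueError("work phase needs watts or speed_m_s")
        return self


class TreadmillRamp(_Block):
    start_m_s: float = 0.67
    increment_m_s: float = 0.22
    every_s: float = 90.0
    cap_m_s: float = 2.22
    grade_pct: float = 9.0


class DamageBlock(_Block):
    uniform: float | None = Field(default=None, ge=0)
    region: Literal["left", "right"] | None = None
    dw: float | None = Field(default=None, ge=0)
    per_segment: dict[int, float] | None = None
    shunt: float | None = Field(default=None, ge=0, le=1)
    dl_reduction: float | None = Field(default=None, ge=0, le=1)

    @model_validator(mode="after")
    def _consistent(self):
        direct = self.shunt is not None or self.dl_reduction is not None
        pattern = (
            self.uniform is not None or self.region is not None or self.per_segment is not None
        )
        if direct and pattern:
            raise ValueError("give either a weight-gain pattern or direct shunt/dl_reduction")
        if self.region is not None and self.dw is None:
            raise ValueError("regional damage needs dw")
        return self


class ControlBlock(_Block):
    ve_rest_l_min: float | None = None
    g_co2_l_min_mmhg: float | None = None
    b_co2_mmhg: float | None = None
    g_hyp_l_min: float | None = None
    s_ref: float | None = None
    k_ex_l_min_w: float | None = None
    tau_up_s: float | None = None
    tau_down_s: float | None = None
    vt_cap_fraction: float | None = None
    q_rest_l_min: float | None = None
    k_q_l_per_l_o2: float | None = None
    fixed_ve_l_min: float | None = None
    fixed_q_l_min: float | None = None


class MetabolicBlock(_Block):
    vo2_rest_l_min: float | None = None
    k_o2_l_min_w: float | None = None
    rq: float | None = None


class FatigueBlock(_Block):
    d_max_ml: float | None = None
    supply_efficiency: float | None = None
    p_v_min_mmhg: float | None = None


class BloodBlock(_Block):
    hb_g_dl: float | None = None
    p50_mmhg: float | None = None
    hill_n: float | None = None
    o2_capacity_ml_g: float | None = None
    beta_o2: float | None = None
    co2_slope: float | None = None
    co2_intercept: float | None = None


class SolverBlock(_Block):
    dt_s: float | None = None
    n_capillary: int | None = None
    capillary_substep: int | None = None
    max_breaths: int | None = None
    ss_rel_change: float | None = None
    use_dl_relation: bool | None = None


class ScenarioConfig(_Block):
    """Validated scenario description; see module docstring for the schema."""

    schema_version: int = 1
    species: Literal["human", "sheep", "goat"] = "human"
    body_mass_kg: float | None = Field(default=None, gt=0)
    duration_s: float = Field(default=120.0, gt=0)
    environment: list[EnvironmentPhase] = Field(default_factory=lambda: [EnvironmentPhase()])
    workload: list[WorkPhase] = Field(default_factory=lambda: [WorkPhase(watts=0.0)])
    treadmill_ramp: TreadmillRamp | None = None
    damage: DamageBlock | None = None
    k_w: float = K_W_DEFAULT
    control: ControlBlock | None = None
    metabolic: MetabolicBlock | None = None
    fatigue: FatigueBlock | None = None
    blood: BloodBlock | None = None
    solver: SolverBlock | None = None
    record_segments: bool = False
    stop_on_fatigue: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _timelines_monotone(self):
        for name, tl in (("environment", self.environment), ("workload", self.workload)):
            ts = [p.t for p in tl]
            if ts != sorted(ts):
                raise ValueError(f"{name} timeline must be monotone in t")
        if self.schema_version != 1:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        return self

    # -- builders -----------------------------------------------------------

    def build_model(self) -> anatomy.LungModel:
        mass = self.body_mass_kg or anatomy.REFERENCE_MASS_KG[self.species]
        builder = {
            "human": anatomy.build_human_lung,
            "sheep": anatomy.build_sheep_lung,
            "goat": anatomy.build_goat_lung,
        }[self.species]
        return builder(mass)

    def build_damage(self, model: anatomy.LungModel) -> DamageState:
        n = len(model.segments)
        if self.damage is None:
            return DamageState.healthy(n, model.shunt_baseline)
        d = self.damage
        if d.shunt is not None or d.dl_reduction is not None:
            return DamageState.uniform(
                n,
                shunt=d.shunt if d.shunt is not None else model.shunt_baseline,
                dl_reduction=d.dl_reduction or 0.0,
            )
        pattern: dict = {}
        if d.uniform is not None:
            pattern = {"uniform": d.uniform}
        elif d.region is not None:
            pattern = {"region": d.region, "dw": d.dw}
        elif d.per_segment is not None:
            pattern = {"per_segment": d.per_segment}
        dw = weight_gain_pattern(model, pattern)
        vol = [s.volume_fraction for s in model.segments]
        return damage_from_weight_change(dw, vol, k_w=self.k_w, baseline_shunt=model.shunt_baseline)

    def work_profile(self, body_mass_kg: float):
        if self.treadmill_ramp is not None:
            r = self.treadmill_ramp

            def profile(t: float) -> float:
                speed = ctl.treadmill_ramp_speed(
                    t, r.start_m_s, r.increment_m_s, r.every_s, r.cap_m_s
                )
                return ctl.treadmill_work(speed, r.grade_pct, body_mass_kg)

            return profile

        phases = sorted(self.workload, key=lambda p: p.t)

        def profile(t: float) -> float:
            cur = phases[0]
            for p in phases:
                if p.t <= t:
                    cur = p
            if cur.watts is not None:
                return cur.watts
            return ctl.treadmill_work(cur.speed_m_s, cur.grade_pct or 0.0, body_mass_kg)

        return profile

    def build_simulator(self):
        from .simulate import LungSimulator, SolverSettings

        model = self.build_model()
        mass = model.body_mass_kg
        over = {k: v for k, v in (self.control.model_dump().items() if self.control else [])
                if v is not None and not k.startswith("fixed_")}
        control = ctl.ControlParams.for_mass(mass, **over)
        met_over = {k: v for k, v in (self.metabolic.model_dump().items() if self.metabolic else [])
                    if v is not None}
        metabolic = ctl.MetabolicParams.for_mass(mass, **met_over)
        fat_over = {k: v for k, v in (self.fatigue.model_dump().items() if self.fatigue else [])
                    if v is not None}
        fatigue = ctl.FatigueParams.for_mass(mass, **fat_over)
        chem_over = {k: v for k, v in (self.blood.model_dump().items() if self.blood else [])
                     if v is not None}
        chem = BloodChemistry(**chem_over) if chem_over else BloodChemistry()
        solver_over = {k: v for k, v in (self.solver.model_dump().items() if self.solver else [])
                       if v is not None}
        settings = SolverSettings(**solver_over) if solver_over else SolverSettings()
        env = [
            {"t": p.t, "fio2": p.fio2, "fico2": p.fico2, "pb": p.pb, "isocapnic": p.isocapnic}
            for p in self.environment
        ]
        return LungSimulator(
            model,
            damage=self.build_damage(model),
            chemistry=chem,
            control_params=control,
            metabolic_params=metabolic,
            fatigue_params=fatigue,
            settings=settings,
            environment=env,
            work_profile=self.work_profile(mass),
            fixed_ve_l_min=self.control.fixed_ve_l_min if self.control else None,
            fixed_q_l_min=self.control.fixed_q_l_min if self.control else None,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json(exclude_none=True))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def preset_path(name: str):
    ref = _ilres.files("pulmodpm").joinpath("resources/presets").joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise ConfigError(f"unknown preset {name!r}; available: {', '.join(list_presets())}")
    return ref


def list_presets() -> list[str]:
    root = _ilres.files("pulmodpm").joinpath("resources/presets")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_config(source) -> ScenarioConfig:
    """Load and validate a scenario from a mapping, preset name or file path."""
    if isinstance(source, ScenarioConfig):
        return source
    if isinstance(source, dict):
        data = source
    else:
        text = None
        s = str(source)
        if os.path.exists(s):
            with open(s) as fh:
                text = fh.read()
        elif os.sep not in s and not s.endswith((".yaml", ".yml", ".json")):
            text = preset_path(s).read_text()
        else:
            raise ConfigError(f"config file not found: {s}")
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
    try:
        return ScenarioConfig.model_validate(data)
    except ValidationError as exc:
        offenders = ", ".join(
            "->".join(str(loc) for loc in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid scenario config ({offenders}): {exc}") from exc
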