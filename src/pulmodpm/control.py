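"""Ventilatory control, cardiac output, metabolism and the fatigue endpoint.

These closed-loop laws are deliberately simple, config-exposed forms:

* ventilatory drive  VE* = VE_rest + G_CO2*[P_aCO2 - B]+ + G_hyp*[S_ref - SaO2]+ + k_ex*W,
  applied through first-order dynamics with separate rise/decay time
  constants (tau_up < tau_down), which produces the characteristic
  hypoxic-step overshoot followed by a slow decay to a plateau;
* breathing pattern: a fixed 35% inspiratory time fraction, tidal volume
  rising linearly with VE up to a vital-capacity cap, frequency carrying the
  remainder (monotone and continuous in VE);
* metabolism: VO2 linear in external workload, VCO2 = RQ*VO2;
* cardiac output: Q = Q_rest + k_Q*VO2;
* fatigue: an oxygen-deficit accumulator.  Whenever metabolic demand exceeds
  the circulatory delivery capacity eff*Q*(C_aO2 - C_v,min) the deficit
  grows; fatigue (power decrement) is declared once it exceeds D_max.

All gains scale linearly with body mass from the 70 kg human defaults except
per-watt coefficients, which are mass-free because workload is absolute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .blood import BloodChemistry, DEFAULT_CHEMISTRY
from .errors import DomainError, InvalidStateError

__all__ = [
    "ControlParams",
    "MetabolicParams",
    "FatigueParams",
    "PhysioState",
    "ventilatory_drive",
    "apply_drive_dynamics",
    "breathing_pattern",
    "metabolic_demand",
    "cardiac_output",
    "oxygen_delivery_capacity",
    "fatigue_update",
    "time_to_fatigue",
    "treadmill_work",
    "treadmill_ramp_speed",
]

REFERENCE_MASS_KG = 70.0


@dataclass(frozen=True)
class ControlParams:
    """Ventilatory controller and breathing-pattern parameters (70 kg defaults)."""

    ve_rest_l_min: float = 6.0
    g_co2_l_min_mmhg: float = 1.5
    b_co2_mmhg: float = 39.0
    g_hyp_l_min: float = 120.0  # L/min per unit SaO2 below the setpoint
    s_ref: float = 0.92
    k_ex_l_min_w: float = 0.25
    tau_up_s: float = 20.0
    tau_down_s: float = 90.0
    #: lung-to-chemoreceptor circulatory/sensing delay; the drive acts on
    #: arterial values this old, which is what makes a rapid desaturation
    #: overshoot before the feedback catches up
    sensor_delay_s: float = 15.0
    #: hypoxic ventilatory decline (roll-off): sustained hypoxia attenuates
    #: the acute hypoxic drive by this fraction with time constant tau_hvd,
    #: producing the characteristic overshoot-then-decay-to-plateau shape
    hvd_fraction: float = 0.4
    tau_hvd_s: float = 180.0
    insp_fraction: float = 0.35
    vt_intercept_ml: float = 250.0
    vt_slope_ml_per_l_min: float = 125.0 / 3.0
    vital_capacity_ml: float = 4600.0
    vt_cap_fraction: float = 0.6
    q_rest_l_min: float = 5.0
    k_q_l_per_l_o2: float = 5.0

    @classmethod
    def for_mass(cls, body_mass_kg: float, **overrides) -> "ControlParams":
        m = body_mass_kg / REFERENCE_MASS_KG
        base = cls(**overrides) if overrides else cls()
        return replace(
            base,
            ve_rest_l_min=base.ve_rest_l_min * m,
            g_co2_l_min_mmhg=base.g_co2_l_min_mmhg * m,
            g_hyp_l_min=base.g_hyp_l_min * m,
            vt_intercept_ml=base.vt_intercept_ml * m,
            vital_capacity_ml=base.vital_capacity_ml * m,
            q_rest_l_min=base.q_rest_l_min * m,
        )


@dataclass(frozen=True)
class MetabolicParams:
    vo2_rest_l_min: float = 0.3
    k_o2_l_min_w: float = 0.0116
    rq: float = 0.85

    @classmethod
    def for_mass(cls, body_mass_kg: float, **overrides) -> "MetabolicParams":
        base = cls(**overrides) if overrides else cls()
        return replace(base, vo2_rest_l_min=base.vo2_rest_l_min * body_mass_kg / REFERENCE_MASS_KG)


@dataclass(frozen=True)
class FatigueParams:
    """Oxygen-deficit fatigue model parameters (70 kg defaults)."""

    d_max_ml: float = 1000.0  # deficit capacity, ml O2
    supply_efficiency: float = 1.0
    demand_ml_min_per_w: float = 11.6  # = 1000 * k_o2; bookkeeping convenience
    p_v_min_mmhg: float = 15.0  # venous PO2 at maximal extraction

    def __post_init__(self) -> None:
        if min(self.d_max_ml, self.supply_efficiency, self.demand_ml_min_per_w, self.p_v_min_mmhg) <= 0:
            raise DomainError("fatigue parameters must be positive")

    @classmethod
    def for_mass(cls, body_mass_kg: float, **overrides) -> "FatigueParams":
        base = cls(**overrides) if overrides else cls()
        return replace(base, d_max_ml=base.d_max_ml * body_mass_kg / REFERENCE_MASS_KG)


@dataclass
class PhysioState:
    """Whole-body state carried breath to breath."""

    c_a_o2: float = 0.197  # arterial O2 content, ml/ml
    c_a_co2: float = 0.48
    c_v_o2: float = 0.147  # mixed venous
    c_v_co2: float = 0.52
    p_a_o2: float = 95.0
    p_a_co2: float = 40.0
    sao2: float = 0.97
    q_tot_l_min: float = 6.5
    ve_l_min: float = 7.0
    v_t_ml: float = 540.0
    freq_per_min: float = 13.0
    vo2_l_min: float = 0.3
    vco2_l_min: float = 0.255
    work_w: float = 0.0
    power_output_w: float = 0.0
    deficit_ml: float = 0.0
    fatigued: bool = False
    time_s: float = 0.0

    def check(self) -> None:
        vals = [self.q_tot_l_min, self.ve_l_min, self.v_t_ml, self.freq_per_min]
        if any(v < 0 for v in vals) or self.deficit_ml < 0:
            raise InvalidStateError("negative physiologic state")
        if abs(self.ve_l_min - self.v_t_ml * self.freq_per_min / 1000.0) > 1e-6 * max(1.0, self.ve_l_min):
            raise InvalidStateError("VE != V_T * Freq / 1000")


def ventilatory_drive(
    sao2: float,
    p_a_co2: float,
    work_w: float,
    params: ControlParams,
    hvd_adapt: float = 0.0,
) -> float:
    """Target minute ventilation (L/min) from chemo- and exercise drives.

    ``hvd_adapt`` in [0, 1) is the current hypoxic-ventilatory-decline
    adaptation level; it attenuates only the hypoxic term.
    """
    co2_term = params.g_co2_l_min_mmhg * max(0.0, p_a_co2 - params.b_co2_mmhg)
    hyp_term = params.g_hyp_l_min * max(0.0, params.s_ref - sao2) * (1.0 - hvd_adapt)
    ex_term = params.k_ex_l_min_w * work_w
    return params.ve_rest_l_min + co2_term + hyp_term + ex_term


def apply_drive_dynamics(ve_l_min: float, ve_target: float, dt_s: float, params: ControlParams) -> float:
    """First-order relaxation of VE toward its target (asymmetric time constants)."""
    tau = params.tau_up_s if ve_target > ve_l_min else params.tau_down_s
    return ve_target + (ve_l_min - ve_target) * math.exp(-dt_s / tau)


def breathing_pattern(ve_l_min: float, params: ControlParams | None = None):
    """Split minute ventilation into (V_T ml, Freq /min, inspiratory fraction).

    V_T rises linearly with VE until it reaches the vital-capacity cap, after
    which frequency alone carries further increases.  The inspiratory time
    fraction is fixed at 0.35 of the breath period.
    """
    if params is None:
        params = ControlParams()
    if ve_l_min <= 0:
        raise DomainError("VE must be positive")
    cap = params.vt_cap_fraction * params.vital_capacity_ml
    v_t = min(params.vt_intercept_ml + params.vt_slope_ml_per_l_min * ve_l_min, cap)
    freq = 1000.0 * ve_l_min / v_t
    return v_t, freq, params.insp_fraction


def metabolic_demand(work_w: float, params: MetabolicParams | None = None):
    """(VO2, VCO2) in L/min for an external workload in watts."""
    if params is None:
        params = MetabolicParams()
    if work_w < 0:
        raise DomainError("work must be non-negative")
    vo2 = params.vo2_rest_l_min + params.k_o2_l_min_w * work_w
    return vo2, params.rq * vo2


def cardiac_output(vo2_l_min: float, params: ControlParams | None = None) -> float:
    """Cardiac output Q = Q_rest + k_Q * VO2 (L/min)."""
    if params is None:
        params = ControlParams()
    return params.q_rest_l_min + params.k_q_l_per_l_o2 * vo2_l_min


def oxygen_delivery_capacity(
    q_tot_l_min: float,
    c_a_o2: float,
    params: FatigueParams,
    chemistry: BloodChemistry = DEFAULT_CHEMISTRY,
) -> float:
    """Maximal aerobic supply rate (L O2/min) at the current arterial content.

    Delivery is limited by cardiac output and by the maximal extractable
    content difference down to the venous floor P_v,min.
    """
    c_v_min = chemistry.o2_content(params.p_v_min_mmhg)
    return params.supply_efficiency * q_tot_l_min * max(0.0, c_a_o2 - c_v_min)


def fatigue_update(
    deficit_ml: float,
    vo2_demand_l_min: float,
    vo2_delivered_l_min: float,
    dt_s: float,
    params: FatigueParams,
):
    """Accumulate oxygen deficit; returns ``(new_deficit_ml, fatigued)``."""
    if dt_s <= 0:
        raise DomainError("dt must be positive")
    rate_ml_s = max(0.0, vo2_demand_l_min - vo2_delivered_l_min) * 1000.0 / 60.0
    new_deficit = deficit_ml + rate_ml_s * dt_s
    return new_deficit, new_deficit > params.d_max_ml


def time_to_fatigue(config) -> float:
    """First time (s) the oxygen deficit exceeds capacity; inf if it never does.

    ``config`` is a ScenarioConfig (or preset name); the scenario is run to
    completion and the summary fatigue time returned.
    """
    from . import simulate

    ts = simulate.run_scenario(config)
    return ts.summary.get("time_to_fatigue_s", math.inf)


# -- treadmill locomotion ---------------------------------------------------

#: Level locomotion cost, W per (kg * m/s); the vertical term adds g*grade.
LOCOMOTION_COEFF_W_PER_KG_M_S = 2.0
GRAVITY_M_S2 = 9.81


def treadmill_work(speed_m_s: float, grade_pct: float, body_mass_kg: float,
                   coeff: float = LOCOMOTION_COEFF_W_PER_KG_M_S) -> float:
    """External-equivalent workload (W) for treadmill speed and grade."""
    if speed_m_s < 0 or grade_pct < 0:
        raise DomainError("speed and grade must be non-negative")
    return body_mass_kg * speed_m_s * (coeff + GRAVITY_M_S2 * grade_pct / 100.0)


def treadmill_ramp_speed(
    t_s: float,
    start_m_s: float = 0.67,
    increment_m_s: float = 0.22,
    every_s: float = 90.0,
    cap_m_s: float = 2.22,
) -> float:
    """Incremental treadmill protocol: step speed increases, capped."""
    steps = int(t_s // every_s)
    return min(start_m_s + steps * increment_m_s, cap_m_s)
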