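"""Breath-by-breath time-stepping engine coupling all model components.

Each breath is one inspiration (35% of the period) followed by one
expiration (65%), advanced on a fixed step ``dt``.  Within a step the
operator splitting is fixed: (1) implicit airway transport, swept root to
leaf on inhalation and leaf to root on exhalation, (2) alveolar
volume/concentration update with membrane diffusion, (3) implicit serial
capillary advance, (4) arterial mixing with the shunt and the well-mixed
tissue/venous pool.  The controller (ventilatory drive, breathing pattern,
cardiac output, metabolism, fatigue) updates once per breath.

Airway and capillary updates are backward Euler and therefore stable for
any ``dt`` up to an inspiration time; the default 10 ms resolves the
within-breath concentration dynamics.  The whole engine is deterministic:
identical configurations produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import control as ctl
from .anatomy import DL_O2_REFERENCE, LungModel
from .blood import BloodChemistry
from .constants import (
    FIO2_AIR,
    P_BAROMETRIC,
    RT_BTPS,
    SECONDS_PER_MINUTE,
    inspired_concentration,
)
from .damage import DamageState
from .distribution import segment_flow_fractions
from .errors import ConvergenceError, SolverError
from .gas_transport import _implicit_division_update, dl_oxygen

__all__ = [
    "SolverSettings",
    "TimeSeries",
    "BreathDiagnostics",
    "LungSimulator",
    "steady_state",
    "run_scenario",
    "make_steady_state_predictor",
]

GASES = ("O2", "CO2")


@dataclass(frozen=True)
class SolverSettings:
    dt_s: float = 0.01
    n_capillary: int = 10
    capillary_substep: int = 5  # advance capillary trains every k-th dt
    tolerance: float = 1e-9
    max_breaths: int = 600
    ss_rel_change: float = 1e-3  # steady-state criterion on P_aO2 / P_aCO2
    ss_consecutive: int = 5
    residual_fraction: float = 0.4  # alveolar floor as fraction of FRC share
    v_store_ml_per_kg: float = 70.0  # tissue/venous pool volume per kg body mass
    use_dl_relation: bool = True  # workload/PO2-dependent D_L,O2

    def __post_init__(self) -> None:
        if self.dt_s <= 0 or self.tolerance <= 0:
            raise SolverError("dt and tolerance must be positive")


@dataclass
class BreathDiagnostics:
    """Per-breath gas accounting (ml STPD per gas: [O2, CO2])."""

    mouth_in: np.ndarray
    mouth_out: np.ndarray
    storage_change: np.ndarray
    transferred_to_blood: np.ndarray
    duration_s: float

    @property
    def closure_error(self) -> np.ndarray:
        """(in - out) - d(storage) - transferred; ~0 when mass is conserved."""
        return self.mouth_in - self.mouth_out - self.storage_change - self.transferred_to_blood


@dataclass
class TimeSeries:
    """Breath-resolved output channels plus a scenario summary block."""

    time_s: np.ndarray
    channels: dict[str, np.ndarray]
    summary: dict = field(default_factory=dict)
    fractions: dict | None = None  # ventilation/perfusion fractions echo

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def to_dataframe(self, wide: bool = True) -> pd.DataFrame:
        cols = {k: v for k, v in self.channels.items() if v.ndim == 1}
        df = pd.DataFrame({"time_s": self.time_s, **cols})
        if wide:
            return df
        return df.melt(id_vars="time_s", var_name="channel", value_name="value")


@dataclass
class EngineState:
    c_up: np.ndarray  # (nU, 2) airway concentrations
    c_ds: np.ndarray  # (nS, 2) conducting dead-space concentrations
    v_alv: np.ndarray  # (nS,) alveolar volumes, ml
    c_alv: np.ndarray  # (nS, 2)
    c_cap: np.ndarray  # (nS, n_div, 2) capillary contents
    p_cap: np.ndarray  # (nS, n_div, 2) capillary pressures (solver cache)
    c_ven: np.ndarray  # (2,) mixed venous contents
    c_art: np.ndarray  # (2,)
    physio: ctl.PhysioState

    def copy(self) -> "EngineState":
        return EngineState(
            c_up=self.c_up.copy(), c_ds=self.c_ds.copy(), v_alv=self.v_alv.copy(),
            c_alv=self.c_alv.copy(), c_cap=self.c_cap.copy(), p_cap=self.p_cap.copy(),
            c_ven=self.c_ven.copy(), c_art=self.c_art.copy(), physio=replace(self.physio),
        )


class LungSimulator:
    """Couples one LungModel with chemistry, damage and the control loop.

    ``fixed_ve_l_min`` / ``fixed_q_l_min`` switch the respective control laws
    to open loop (useful for oracle comparisons); ``work_profile`` maps time
    in seconds to external workload in watts.
    """

    def __init__(
        self,
        model: LungModel,
        damage: DamageState | None = None,
        chemistry: BloodChemistry | None = None,
        control_params: ctl.ControlParams | None = None,
        metabolic_params: ctl.MetabolicParams | None = None,
        fatigue_params: ctl.FatigueParams | None = None,
        settings: SolverSettings | None = None,
        environment: list[dict] | None = None,
        work_profile=None,
        fixed_ve_l_min: float | None = None,
        fixed_q_l_min: float | None = None,
    ) -> None:
        self.model = model
        self.settings = settings or SolverSettings()
        self.chem = chemistry or BloodChemistry()
        mass = model.body_mass_kg
        self.control = control_params or ctl.ControlParams.for_mass(mass)
        self.metabolic = metabolic_params or ctl.MetabolicParams.for_mass(mass)
        self.fatigue = fatigue_params or ctl.FatigueParams.for_mass(mass)
        self.damage = damage or DamageState.healthy(len(model.segments), model.shunt_baseline)
        self.environment = sorted(
            environment or [{"t": 0.0, "fio2": FIO2_AIR, "fico2": 0.0, "pb": P_BAROMETRIC}],
            key=lambda e: e["t"],
        )
        self.work_profile = work_profile or (lambda t: 0.0)
        self.fixed_ve = fixed_ve_l_min
        self.fixed_q = fixed_q_l_min
        self._isocapnic_target: float | None = None
        self._fico2_extra = 0.0
        self._sensor_hist: list[tuple[float, float, float]] = []  # (t, sao2, p_a_co2)
        self._hvd_adapt = 0.0
        self._last_hvd_target = 0.0

        self._precompute_structure()

    # -- structure ----------------------------------------------------------

    def _precompute_structure(self) -> None:
        m = self.model
        comps = sorted(m.airway_compartments, key=lambda c: c.id)
        self.upper_ids = [c.id for c in comps]
        pos = {cid: i for i, cid in enumerate(self.upper_ids)}
        nU, nS = len(comps), len(m.segments)
        self.v_up = np.array([c.volume_ml for c in comps])
        self.parent_pos = np.array(
            [pos[c.parent_id] if c.parent_id is not None else -1 for c in comps]
        )
        # topological levels (root first)
        depth = {}
        for c in comps:
            depth[c.id] = len(m.path_to_root(c.id)) - 1
        max_d = max(depth.values())
        self.levels = [
            np.array([pos[c.id] for c in comps if depth[c.id] == d], dtype=int)
            for d in range(max_d + 1)
        ]
        self.root_pos = pos[m.root_id]

        self.v_ds = np.array([s.conducting_deadspace_volume_ml for s in m.segments])
        self.feed_pos = np.array([pos[s.feeding_airway_id] for s in m.segments])
        self.f_k = np.array([s.volume_fraction for s in m.segments])
        # subtended-segment incidence: flow through airway i = sum of its
        # subtended segmental flows (conservation by construction)
        sub = np.zeros((nU, nS))
        for k, s in enumerate(m.segments):
            for aid in m.path_to_root(s.feeding_airway_id):
                sub[pos[aid], k] = 1.0
        self.subtend = sub

        ff = segment_flow_fractions(m.segments)
        self.f_v = ff.ventilation
        self.f_q = ff.perfusion
        self.v_alv0 = self.f_k * m.v_alveolar_total_ml
        self.residual_floor = self.settings.residual_fraction * self.v_alv0
        self.dl_area_factor = m.dl_o2_ref / DL_O2_REFERENCE
        self.v_store_ml = self.settings.v_store_ml_per_kg * m.body_mass_kg

    # -- state --------------------------------------------------------------

    def init_state(self) -> EngineState:
        env = self._env_at(0.0)
        nU, nS, n = len(self.upper_ids), len(self.model.segments), self.settings.n_capillary
        c_insp = np.array(
            [inspired_concentration(env["fio2"], env["pb"]),
             inspired_concentration(env["fico2"], env["pb"])]
        )
        p_alv0 = np.array([100.0, 40.0])
        c_alv0 = p_alv0 / RT_BTPS
        p_art0 = np.array([95.0, 40.0])
        c_art0 = np.array(
            [self.chem.content("O2", p_art0[0]), self.chem.content("CO2", p_art0[1])]
        )
        vo2, vco2 = ctl.metabolic_demand(0.0, self.metabolic)
        q0 = self.fixed_q if self.fixed_q is not None else ctl.cardiac_output(vo2, self.control)
        c_ven0 = c_art0 + np.array([-vo2, vco2]) / q0
        ve0 = self.fixed_ve if self.fixed_ve is not None else self.control.ve_rest_l_min * 1.2
        v_t, freq, _ = ctl.breathing_pattern(ve0, self.control)
        physio = ctl.PhysioState(
            c_a_o2=c_art0[0], c_a_co2=c_art0[1], c_v_o2=c_ven0[0], c_v_co2=c_ven0[1],
            p_a_o2=p_art0[0], p_a_co2=p_art0[1],
            sao2=float(self.chem.o2_saturation(p_art0[0])),
            q_tot_l_min=q0, ve_l_min=ve0, v_t_ml=v_t, freq_per_min=freq,
            vo2_l_min=vo2, vco2_l_min=vco2,
        )
        p_cap = np.tile(p_art0, (nS, n, 1)).astype(float)
        c_cap = np.stack(
            [np.full((nS, n), c_art0[0]), np.full((nS, n), c_art0[1])], axis=-1
        )
        return EngineState(
            c_up=np.tile(c_insp, (nU, 1)),
            c_ds=np.tile(c_alv0, (nS, 1)),
            v_alv=self.v_alv0.copy(),
            c_alv=np.tile(c_alv0, (nS, 1)),
            c_cap=c_cap, p_cap=p_cap,
            c_ven=c_ven0, c_art=c_art0.copy(), physio=physio,
        )

    def _env_at(self, t_s: float) -> dict:
        cur = self.environment[0]
        for e in self.environment:
            if e["t"] <= t_s:
                cur = e
        return cur

    # -- one breath ---------------------------------------------------------

    def run_breath(self, state: EngineState) -> BreathDiagnostics:
        """Advance ``state`` in place by one full breath; returns accounting."""
        st = self.settings
        ph = state.physio
        t0 = ph.time_s
        env = self._env_at(t0)

        # controller update (once per breath, using last breath's duration)
        work_target = float(self.work_profile(t0))
        work_eff = work_target if not ph.fatigued else min(work_target, ph.power_output_w)
        vo2_dem, vco2_dem = ctl.metabolic_demand(work_eff, self.metabolic)
        q_tot = self.fixed_q if self.fixed_q is not None else ctl.cardiac_output(vo2_dem, self.control)
        dt_ctrl = 60.0 / ph.freq_per_min if ph.freq_per_min > 0 else 5.0
        if self.fixed_ve is not None:
            ve = self.fixed_ve
        else:
            sao2_sens, paco2_sens = self._sensed(t0, ph)
            # hypoxic ventilatory decline: slow, graded adaptation of the
            # acute drive (full roll-off ~5% saturation below the setpoint)
            stim = max(0.0, self.control.s_ref - sao2_sens)
            hvd_target = self.control.hvd_fraction * min(1.0, stim / 0.05)
            self._last_hvd_target = hvd_target
            self._hvd_adapt += (hvd_target - self._hvd_adapt) * (
                1.0 - math.exp(-dt_ctrl / self.control.tau_hvd_s)
            )
            target = ctl.ventilatory_drive(
                sao2_sens, paco2_sens, work_eff, self.control, hvd_adapt=self._hvd_adapt
            )
            ve = ctl.apply_drive_dynamics(ph.ve_l_min, target, dt_ctrl, self.control)
        v_t, freq, insp_frac = ctl.breathing_pattern(ve, self.control)
        period = SECONDS_PER_MINUTE / freq
        t_insp, t_exp = insp_frac * period, (1.0 - insp_frac) * period

        # isocapnic clamp: integral controller on inspired CO2 fraction
        fico2 = env["fico2"]
        if env.get("isocapnic"):
            if self._isocapnic_target is None:
                self._isocapnic_target = ph.p_a_co2
            err = self._isocapnic_target - ph.p_a_co2
            self._fico2_extra = min(max(self._fico2_extra + 0.004 * err, 0.0), 0.10)
            fico2 = min(fico2 + self._fico2_extra + max(0.0, 0.006 * err), 0.12)
        else:
            self._isocapnic_target = None
            self._fico2_extra = 0.0

        c_amb = np.array(
            [inspired_concentration(env["fio2"], env["pb"]),
             inspired_concentration(fico2, env["pb"])]
        )

        storage0 = self._gas_storage(state)
        mouth_in = np.zeros(2)
        mouth_out = np.zeros(2)
        transferred = np.zeros(2)
        c_art_sum = np.zeros(2)
        n_steps_total = 0

        q_tot_ml_s = q_tot * 1000.0 / SECONDS_PER_MINUTE
        shunt = self.damage.shunt
        q_cap_ml_s = (1.0 - shunt) * q_tot_ml_s * self.f_q  # per segment
        # per-division implicit coefficients (flow part; diffusion set per step)
        n_div = st.n_capillary
        v_cap = self.model.v_capillary_total_ml
        kf = n_div * q_cap_ml_s / (v_cap * self.f_k)  # 1/s, per segment

        for phase, t_phase in (("inhale", t_insp), ("exhale", t_exp)):
            n_steps = max(1, int(round(t_phase / st.dt_s)))
            dt = t_phase / n_steps
            flow_mouth = v_t / t_phase
            seg_flow = self.f_v * flow_mouth
            up_flow = self.subtend @ seg_flow
            r_up = up_flow[:, None] * dt / self.v_up[:, None]
            r_ds = seg_flow[:, None] * dt / self.v_ds[:, None]
            cap_every = max(1, st.capillary_substep)

            for istep in range(n_steps):
                dl_eff = self._dl_eff(state, work_eff)
                g = (self.f_k[:, None] * dl_eff) / SECONDS_PER_MINUTE
                p_c_eff = state.p_cap.mean(axis=1)  # (nS, 2)
                if phase == "inhale":
                    self._sweep_in(state, c_amb, r_up, r_ds)
                    mouth_in += flow_mouth * dt * c_amb
                    v_new = state.v_alv + seg_flow * dt
                    num = state.v_alv[:, None] * state.c_alv + dt * (
                        seg_flow[:, None] * state.c_ds + g * p_c_eff
                    )
                    den = v_new[:, None] + dt * g * RT_BTPS
                else:
                    v_new = state.v_alv - seg_flow * dt
                    if np.any(v_new < self.residual_floor):
                        bad = int(np.argmin(v_new - self.residual_floor))
                        raise SolverError(
                            f"alveolar volume underflow in segment {self.model.segments[bad].id}"
                        )
                    num = state.v_alv[:, None] * state.c_alv + dt * g * p_c_eff
                    den = v_new[:, None] + dt * (seg_flow[:, None] + g * RT_BTPS)
                c_alv_new = num / den
                flux = dt * g * (RT_BTPS * c_alv_new - p_c_eff)  # ml STPD, (nS, 2)
                transferred += flux.sum(axis=0)
                state.v_alv = v_new
                state.c_alv = c_alv_new
                if phase == "exhale":
                    self._sweep_out(state, seg_flow, up_flow, r_up, r_ds)
                    mouth_out += flow_mouth * dt * state.c_up[self.root_pos]

                # capillary trains (sub-stepped; implicit, stable)
                if (istep + 1) % cap_every == 0 or istep == n_steps - 1:
                    k_since = (istep % cap_every) + 1
                    dt_cap = k_since * dt
                    self._advance_capillaries(state, dt_cap, kf, dl_eff)

                # arterial mixing and tissue pool
                c_end = state.c_cap[:, -1, :]  # outlet divisions
                mean_end = (c_end * self.f_q[:, None]).sum(axis=0)
                state.c_art = (1.0 - shunt) * mean_end + shunt * state.c_ven
                delivery = ctl.oxygen_delivery_capacity(
                    q_tot, state.c_art[0], self.fatigue, self.chem
                )
                vo2_act = min(vo2_dem, delivery)
                vco2_act = self.metabolic.rq * vo2_act
                vdot_ml_s = np.array([-vo2_act, vco2_act]) * 1000.0 / SECONDS_PER_MINUTE
                state.c_ven = state.c_ven + dt * (
                    q_tot_ml_s * (state.c_art - state.c_ven) + vdot_ml_s
                ) / self.v_store_ml
                state.c_ven = np.maximum(state.c_ven, 1e-6)
                c_art_sum += state.c_art
                n_steps_total += 1

        if not np.all(np.isfinite(state.c_alv)) or np.any(state.c_alv < 0):
            raise SolverError(f"unstable state after breath at t={t0:.1f}s")

        # breath-mean arterial values drive control and reporting
        c_art_mean = c_art_sum / n_steps_total
        p_a_o2 = float(self.chem.pressure_from_content("O2", c_art_mean[0]))
        p_a_co2 = float(self.chem.pressure_from_content("CO2", c_art_mean[1]))

        delivery = ctl.oxygen_delivery_capacity(q_tot, c_art_mean[0], self.fatigue, self.chem)
        deficit, fatigued = ctl.fatigue_update(ph.deficit_ml, vo2_dem, delivery, period, self.fatigue)
        if self.metabolic.k_o2_l_min_w > 0:
            sustainable = max(
                0.0, (delivery - self.metabolic.vo2_rest_l_min) / self.metabolic.k_o2_l_min_w
            )
        else:
            sustainable = math.inf
        power_out = work_target if not (ph.fatigued or fatigued) else min(work_target, sustainable)

        state.physio = replace(
            ph,
            c_a_o2=float(c_art_mean[0]), c_a_co2=float(c_art_mean[1]),
            c_v_o2=float(state.c_ven[0]), c_v_co2=float(state.c_ven[1]),
            p_a_o2=p_a_o2, p_a_co2=p_a_co2,
            sao2=float(self.chem.o2_saturation(p_a_o2)),
            q_tot_l_min=q_tot, ve_l_min=ve, v_t_ml=v_t, freq_per_min=freq,
            vo2_l_min=min(vo2_dem, delivery), vco2_l_min=self.metabolic.rq * min(vo2_dem, delivery),
            work_w=work_eff, power_output_w=power_out,
            deficit_ml=deficit, fatigued=ph.fatigued or fatigued,
            time_s=t0 + period,
        )
        storage1 = self._gas_storage(state)
        return BreathDiagnostics(
            mouth_in=mouth_in, mouth_out=mouth_out,
            storage_change=storage1 - storage0,
            transferred_to_blood=transferred, duration_s=period,
        )

    # -- helpers ------------------------------------------------------------

    def _sensed(self, t_now: float, ph: ctl.PhysioState) -> tuple[float, float]:
        """Arterial values as seen by the chemoreceptors (circulatory delay)."""
        delay = self.control.sensor_delay_s
        hist = self._sensor_hist
        hist.append((t_now, ph.sao2, ph.p_a_co2))
        if len(hist) > 400:
            del hist[:-400]
        t_sense = t_now - delay
        sensed = hist[0]
        for entry in hist:
            if entry[0] <= t_sense:
                sensed = entry
            else:
                break
        return sensed[1], sensed[2]

    def _dl_eff(self, state: EngineState, work_w: float) -> np.ndarray:
        """Per-segment effective whole-lung-equivalent D_L, (nS, 2)."""
        red = 1.0 - self.damage.dl_reduction
        if self.settings.use_dl_relation:
            p_alv_o2 = np.maximum(state.c_alv[:, 0] * RT_BTPS, 0.0)
            dl_o2 = dl_oxygen(p_alv_o2, work_w) * self.dl_area_factor
        else:
            dl_o2 = np.full(len(red), self.model.dl_o2_ref)
        dl_co2 = np.full(len(red), self.model.dl_co2)
        return np.stack([dl_o2 * red, dl_co2 * red], axis=-1)

    def _sweep_in(self, state: EngineState, c_amb: np.ndarray, r_up, r_ds) -> None:
        c = state.c_up
        for lev in self.levels:
            parents = self.parent_pos[lev]
            c_in = np.where(parents[:, None] >= 0, c[parents], c_amb)
            c[lev] = (c[lev] + r_up[lev] * c_in) / (1.0 + r_up[lev])
        state.c_ds = (state.c_ds + r_ds * c[self.feed_pos]) / (1.0 + r_ds)

    def _sweep_out(self, state: EngineState, seg_flow, up_flow, r_up, r_ds) -> None:
        # dead space first (inlet = freshly updated alveolar gas)
        state.c_ds = (state.c_ds + r_ds * state.c_alv) / (1.0 + r_ds)
        # accumulate child flow-weighted concentrations into each parent
        buf = np.zeros_like(state.c_up)
        np.add.at(buf, self.feed_pos, seg_flow[:, None] * state.c_ds)
        c = state.c_up
        for lev in reversed(self.levels):
            denom = np.maximum(up_flow[lev][:, None], 1e-300)
            c_in = buf[lev] / denom
            c[lev] = (c[lev] + r_up[lev] * c_in) / (1.0 + r_up[lev])
            parents = self.parent_pos[lev]
            valid = parents >= 0
            if np.any(valid):
                np.add.at(
                    buf, parents[valid],
                    up_flow[lev][valid][:, None] * c[lev][valid],
                )

    def _advance_capillaries(self, state: EngineState, dt_cap: float, kf, dl_eff) -> None:
        p_alv = state.c_alv * RT_BTPS
        a_flow = dt_cap * kf  # (nS,)
        v_cap = self.model.v_capillary_total_ml
        for gi, gas in enumerate(GASES):
            a_diff = dt_cap * dl_eff[:, gi] / (v_cap * SECONDS_PER_MINUTE)
            c_in = np.full(len(kf), state.c_ven[gi])
            for d in range(self.settings.n_capillary):
                p_new, c_new = _implicit_division_update(
                    self.chem, gas,
                    state.c_cap[:, d, gi], c_in, state.p_cap[:, d, gi],
                    p_alv[:, gi], a_flow, a_diff,
                )
                state.c_cap[:, d, gi] = c_new
                state.p_cap[:, d, gi] = p_new
                c_in = c_new

    def _gas_storage(self, state: EngineState) -> np.ndarray:
        return (
            (self.v_up[:, None] * state.c_up).sum(axis=0)
            + (self.v_ds[:, None] * state.c_ds).sum(axis=0)
            + (state.v_alv[:, None] * state.c_alv).sum(axis=0)
        )

    # -- multi-breath drivers ------------------------------------------------

    def run(
        self,
        duration_s: float,
        state: EngineState | None = None,
        record_segments: bool = False,
        stop_on_fatigue: bool = False,
    ) -> tuple[TimeSeries, EngineState]:
        """Run for ``duration_s`` of simulated time, recording per breath."""
        state = state or self.init_state()
        rows: dict[str, list] = {k: [] for k in (
            "ve", "v_t", "freq", "sao2", "p_a_o2", "p_a_co2", "c_a_o2", "c_v_o2",
            "q_tot", "vo2", "vco2", "work", "power_output", "deficit", "fatigued",
        )}
        times = []
        seg_p = []
        fatigue_time = math.inf
        while state.physio.time_s < duration_s:
            if len(times) >= self.settings.max_breaths:
                raise ConvergenceError(
                    f"exceeded max_breaths={self.settings.max_breaths} before t={duration_s}s"
                )
            was_fatigued = state.physio.fatigued
            self.run_breath(state)
            ph = state.physio
            times.append(ph.time_s)
            for key, val in (
                ("ve", ph.ve_l_min), ("v_t", ph.v_t_ml), ("freq", ph.freq_per_min),
                ("sao2", ph.sao2), ("p_a_o2", ph.p_a_o2), ("p_a_co2", ph.p_a_co2),
                ("c_a_o2", ph.c_a_o2), ("c_v_o2", ph.c_v_o2),
                ("q_tot", ph.q_tot_l_min), ("vo2", ph.vo2_l_min), ("vco2", ph.vco2_l_min),
                ("work", ph.work_w), ("power_output", ph.power_output_w),
                ("deficit", ph.deficit_ml), ("fatigued", float(ph.fatigued)),
            ):
                rows[key].append(val)
            if record_segments:
                seg_p.append(state.c_alv[:, 0] * RT_BTPS)
            if ph.fatigued and not was_fatigued:
                fatigue_time = ph.time_s
            if stop_on_fatigue and ph.fatigued:
                break
        channels = {k: np.array(v) for k, v in rows.items()}
        if record_segments:
            channels["p_alv_o2_segments"] = np.array(seg_p)
        ts = TimeSeries(
            time_s=np.array(times),
            channels=channels,
            summary={"time_to_fatigue_s": fatigue_time},
            fractions={
                "segment_ids": [s.id for s in self.model.segments],
                "ventilation": self.f_v.tolist(),
                "perfusion": self.f_q.tolist(),
            },
        )
        return ts, state

    def run_until_steady(self, state: EngineState | None = None, accelerate: bool = True):
        """Breathe until P_aO2 and P_aCO2 settle; returns (summary, state, n_breaths).

        Convergence: relative change per breath below ``ss_rel_change`` for
        ``ss_consecutive`` consecutive breaths.  With ``accelerate`` the
        mixed-venous pool (and the slow ventilatory-adaptation state) is
        relaxed toward its Fick-principle value over the first ~25 breaths,
        which shortcuts the slow tissue-store transient without moving the
        fixed point; acceleration then stops so the natural dynamics settle
        the remainder (sustained acceleration can excite a spurious
        controller-delay limit cycle).
        """
        st = self.settings
        state = state or self.init_state()
        streak = 0
        prev = (state.physio.p_a_o2, state.physio.p_a_co2)
        for n in range(1, st.max_breaths + 1):
            self.run_breath(state)
            ph = state.physio
            if accelerate and 3 <= n <= 25:
                q = ph.q_tot_l_min
                target = np.array([
                    ph.c_a_o2 - ph.vo2_l_min / q,
                    ph.c_a_co2 + ph.vco2_l_min / q,
                ])
                state.c_ven = 0.4 * state.c_ven + 0.6 * np.maximum(target, 1e-6)
                # collapse the slow ventilatory-adaptation mode as well
                self._hvd_adapt += 0.6 * (self._last_hvd_target - self._hvd_adapt)
            cur = (ph.p_a_o2, ph.p_a_co2)
            rel = max(abs(cur[0] - prev[0]) / max(cur[0], 1.0),
                      abs(cur[1] - prev[1]) / max(cur[1], 1.0))
            prev = cur
            streak = streak + 1 if rel < st.ss_rel_change else 0
            if streak >= st.ss_consecutive:
                return self._summary(state, n), state, n
        raise ConvergenceError(
            f"no steady state within {st.max_breaths} breaths "
            f"(last rel change {rel:.2e})"
        )

    def _summary(self, state: EngineState, n_breaths: int) -> dict:
        ph = state.physio
        return {
            "ve_l_min": ph.ve_l_min, "q_tot_l_min": ph.q_tot_l_min,
            "vo2_l_min": ph.vo2_l_min, "vco2_l_min": ph.vco2_l_min,
            "p_a_o2_mmhg": ph.p_a_o2, "p_a_co2_mmhg": ph.p_a_co2,
            "sao2": ph.sao2, "c_a_o2": ph.c_a_o2, "c_v_o2": ph.c_v_o2,
            "v_t_ml": ph.v_t_ml, "freq_per_min": ph.freq_per_min,
            "n_breaths": n_breaths,
        }


# -- module-level drivers ---------------------------------------------------


def steady_state(
    model: LungModel,
    conditions: dict | None = None,
    damage: DamageState | None = None,
    settings: SolverSettings | None = None,
    chemistry: BloodChemistry | None = None,
    state: EngineState | None = None,
):
    """Closed-loop (or open-loop) steady state under constant conditions.

    ``conditions`` keys: fio2, fico2, pb, work_w, fixed_ve_l_min,
    fixed_q_l_min.  Returns ``(summary, state)`` with the converged values
    and breath count.
    """
    cond = dict(conditions or {})
    env = [{
        "t": 0.0,
        "fio2": cond.get("fio2", FIO2_AIR),
        "fico2": cond.get("fico2", 0.0),
        "pb": cond.get("pb", P_BAROMETRIC),
    }]
    work = float(cond.get("work_w", 0.0))
    sim = LungSimulator(
        model, damage=damage, settings=settings, chemistry=chemistry,
        environment=env, work_profile=lambda t: work,
        fixed_ve_l_min=cond.get("fixed_ve_l_min"),
        fixed_q_l_min=cond.get("fixed_q_l_min"),
    )
    summary, state, _ = sim.run_until_steady(state)
    return summary, state


def make_steady_state_predictor(
    model: LungModel,
    environment: dict | None = None,
    solver: SolverSettings | None = None,
):
    """Build ``f(work_w, shunt, dl_reduction) -> steady-state P_aO2 (mmHg)``.

    Used by the damage calibration fit.  Converged engine states are cached
    per workload and reused as warm starts across parameter evaluations,
    which shortens each steady-state solve considerably.
    """
    solver = solver or SolverSettings(dt_s=0.02, ss_rel_change=2e-4, max_breaths=400)
    env = dict(environment or {})
    cache: dict[float, EngineState] = {}

    def predict(work_w: float, shunt: float, dl_reduction: float) -> float:
        dmg = DamageState.uniform(len(model.segments), shunt=shunt, dl_reduction=dl_reduction)
        cond = {**env, "work_w": float(work_w)}
        state0 = cache[work_w].copy() if work_w in cache else None
        summary, state = steady_state(model, cond, damage=dmg, settings=solver, state=state0)
        cache[work_w] = state.copy()
        return summary["p_a_o2_mmhg"]

    return predict


def run_scenario(config) -> TimeSeries:
    """Execute a scenario configuration (object, mapping, preset name or path)."""
    from .config import ScenarioConfig, load_config

    if not isinstance(config, ScenarioConfig):
        config = load_config(config)
    sim = config.build_simulator()
    ts, state = sim.run(
        config.duration_s,
        record_segments=config.record_segments,
        stop_on_fatigue=config.stop_on_fatigue,
    )
    summary, _ = (ts.summary, None)
    ph = state.physio
    summary.update({
        "final_p_a_o2_mmhg": ph.p_a_o2, "final_p_a_co2_mmhg": ph.p_a_co2,
        "final_sao2": ph.sao2, "final_ve_l_min": ph.ve_l_min,
        "final_q_tot_l_min": ph.q_tot_l_min, "final_vo2_l_min": ph.vo2_l_min,
    })
    return ts
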