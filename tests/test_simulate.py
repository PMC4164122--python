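"""Breath engine: fixed points, conservation, convergence, analytic oracle.

The independent oracle is a continuous-ventilation two-compartment steady
state solved with scipy (alveolar gas equation + capillary transit ODE +
shunt mixing + Fick closure), never touching the breath engine.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from pulmodpm import make_fixture_lung
from pulmodpm.blood import BloodChemistry
from pulmodpm.constants import P_H2O, RT_BTPS
from pulmodpm.control import MetabolicParams
from pulmodpm.damage import DamageState
from pulmodpm.errors import SolverError
from pulmodpm.simulate import LungSimulator, SolverSettings, steady_state


def analytic_two_compartment(
    fio2, ve_l_min, freq, vd_ml, q_l_min, vo2, vco2, dl_o2, shunt, chem, pb=760.0
):
    """Continuous-ventilation steady state, independent of the engine.

    Alveolar gas equation fixes P_A from alveolar ventilation; the
    end-capillary content integrates the transit ODE Q_c dC/dz = D_L (P_A -
    P(C)); venous content closes the Fick principle.  Returns (P_aO2,
    P_aCO2) in mmHg.
    """
    pi_o2 = fio2 * (pb - P_H2O)
    va = ve_l_min - freq * vd_ml / 1000.0  # L/min, Bohr dead space
    p_a_o2 = pi_o2 - RT_BTPS * vo2 / va
    p_a_co2 = RT_BTPS * vco2 / va
    q_cap = (1.0 - shunt) * q_l_min * 1000.0  # ml/min through the exchanger

    def end_capillary(c_v):
        def rhs(z, y):
            return [dl_o2 * (p_a_o2 - chem.o2_pressure_from_content(min(y[0], 0.26))) / q_cap]

        sol = solve_ivp(rhs, (0.0, 1.0), [c_v], method="LSODA", rtol=1e-9, atol=1e-12)
        return float(sol.y[0, -1])

    def fick_gap(c_v):
        c_a = (1.0 - shunt) * end_capillary(c_v) + shunt * c_v
        return q_l_min * 1000.0 * (c_a - c_v) - vo2 * 1000.0

    c_a_guess = chem.o2_content(p_a_o2)
    c_v = brentq(fick_gap, 1e-4, c_a_guess, xtol=1e-10)
    c_a = (1.0 - shunt) * end_capillary(c_v) + shunt * c_v
    return chem.o2_pressure_from_content(c_a), p_a_co2


class TestSteadyStateOracle:
    def test_homogeneous_lung_matches_two_compartment_solution(self):
        """Engine steady state vs the analytic solution, within 1 mmHg."""
        lung = make_fixture_lung(1, upper_volume_ml=8.0, deadspace_per_segment_ml=2.0)
        chem = BloodChemistry()
        settings = SolverSettings(use_dl_relation=False, ss_rel_change=1e-4,
                                  max_breaths=400)
        cond = {"fixed_ve_l_min": 6.0, "fixed_q_l_min": 6.5, "work_w": 0.0}
        summary, _ = steady_state(lung, cond, settings=settings, chemistry=chem)
        freq = summary["freq_per_min"]
        p_o2, p_co2 = analytic_two_compartment(
            fio2=0.2094, ve_l_min=6.0, freq=freq, vd_ml=10.0, q_l_min=6.5,
            vo2=0.3, vco2=0.255, dl_o2=40.0, shunt=0.02, chem=chem,
        )
        assert summary["p_a_o2_mmhg"] == pytest.approx(p_o2, abs=1.0)
        assert summary["p_a_co2_mmhg"] == pytest.approx(p_co2, abs=1.0)

    def test_shunt_strictly_lowers_arterial_o2(self):
        lung = make_fixture_lung(1)
        settings = SolverSettings(use_dl_relation=False, dt_s=0.02)
        cond = {"fixed_ve_l_min": 6.5, "fixed_q_l_min": 6.5}
        values = []
        for shunt in (0.0, 0.05, 0.15):
            dmg = DamageState.uniform(1, shunt=shunt, dl_reduction=0.0)
            s, _ = steady_state(lung, cond, damage=dmg, settings=settings)
            values.append(s["p_a_o2_mmhg"])
        assert values[0] > values[1] > values[2]

    def test_dl_reduction_never_raises_arterial_o2(self):
        lung = make_fixture_lung(1)
        settings = SolverSettings(use_dl_relation=False, dt_s=0.02)
        cond = {"fixed_ve_l_min": 6.5, "fixed_q_l_min": 6.5}
        values = []
        for red in (0.0, 0.5, 0.8):
            dmg = DamageState.uniform(1, shunt=0.02, dl_reduction=red)
            s, _ = steady_state(lung, cond, damage=dmg, settings=settings)
            values.append(s["c_a_o2"])
        assert values[0] >= values[1] >= values[2]
        assert values[0] > values[2]  # strict over the full range


class TestRunBreath:
    def _fixture_sim(self, **kwargs):
        lung = make_fixture_lung(2, symmetric=True)
        defaults = dict(fixed_ve_l_min=6.0, fixed_q_l_min=6.5)
        defaults.update(kwargs)
        return LungSimulator(lung, **defaults)

    def test_equilibrium_is_fixed_point(self):
        """Zero metabolism with all compartments at inspired-gas equilibrium
        stays put over a breath."""
        lung = make_fixture_lung(2, symmetric=True)
        chem = BloodChemistry()
        sim = LungSimulator(
            lung, chemistry=chem,
            metabolic_params=MetabolicParams(vo2_rest_l_min=0.0, k_o2_l_min_w=0.0),
            fixed_ve_l_min=6.0, fixed_q_l_min=6.5,
        )
        state = sim.init_state()
        p_eq = np.array([0.2094 * (760 - P_H2O), 0.0])
        c_eq = p_eq / RT_BTPS
        state.c_up[:] = c_eq
        state.c_ds[:] = c_eq
        state.c_alv[:] = c_eq
        for gi, gas in enumerate(("O2", "CO2")):
            state.c_cap[:, :, gi] = chem.content(gas, p_eq[gi])
            state.p_cap[:, :, gi] = p_eq[gi]
        state.c_ven = np.array([chem.content("O2", p_eq[0]), chem.content("CO2", 0.0)])
        state.c_art = state.c_ven.copy()
        sim.run_breath(state)
        np.testing.assert_allclose(state.c_alv, np.tile(c_eq, (2, 1)), rtol=1e-9)
        np.testing.assert_allclose(state.p_cap[:, :, 0], p_eq[0], atol=1e-6)

    def test_per_breath_mass_closure(self):
        """(in - out) - d(storage) - transferred vanishes for both gases."""
        sim = self._fixture_sim()
        state = sim.init_state()
        for _ in range(5):
            diag = sim.run_breath(state)
        scale = np.abs(diag.transferred_to_blood) + 1e-9
        assert np.all(np.abs(diag.closure_error) / scale < 0.005)

    def test_o2_uptake_matches_resting_metabolism(self):
        """At steady state one breath transfers VO2_rest * period of O2."""
        lung = make_fixture_lung(1)
        settings = SolverSettings(ss_rel_change=1e-4, dt_s=0.02)
        _, state = steady_state(
            lung, {"fixed_ve_l_min": 6.5, "fixed_q_l_min": 6.5}, settings=settings
        )
        sim = LungSimulator(lung, fixed_ve_l_min=6.5, fixed_q_l_min=6.5,
                            settings=settings)
        diag = sim.run_breath(state)
        expected_ml = 0.3 * 1000.0 / 60.0 * diag.duration_s
        assert diag.transferred_to_blood[0] == pytest.approx(expected_ml, rel=0.02)

    def test_symmetric_segments_stay_identical(self):
        sim = self._fixture_sim()
        state = sim.init_state()
        for _ in range(10):
            sim.run_breath(state)
        np.testing.assert_allclose(state.c_alv[0], state.c_alv[1], rtol=1e-12)
        np.testing.assert_allclose(state.c_cap[0], state.c_cap[1], rtol=1e-12)

    def test_halving_dt_barely_moves_steady_state(self):
        lung = make_fixture_lung(1)
        cond = {"fixed_ve_l_min": 6.5, "fixed_q_l_min": 6.5}
        out = []
        for dt in (0.01, 0.005):
            s, _ = steady_state(
                lung, cond,
                settings=SolverSettings(dt_s=dt, ss_rel_change=1e-4, max_breaths=400),
            )
            out.append(s["p_a_o2_mmhg"])
        assert abs(out[0] - out[1]) < 0.2

    def test_implicit_sweep_stable_at_large_dt(self):
        """No blow-up even when dt approaches one inspiration time."""
        sim = self._fixture_sim(settings=SolverSettings(dt_s=1.0))
        state = sim.init_state()
        for _ in range(20):
            sim.run_breath(state)
        assert np.all(np.isfinite(state.c_alv)) and np.all(state.c_alv >= 0)
        assert np.isfinite(state.physio.p_a_o2)

    def test_volume_underflow_names_segment(self):
        sim = self._fixture_sim()
        state = sim.init_state()
        # start below the residual floor: the expiration must trip the guard
        state.v_alv[:] = 0.3 * sim.v_alv0
        with pytest.raises(SolverError, match="segment"):
            for _ in range(3):
                sim.run_breath(state)


class TestDeterminism:
    def test_identical_runs_bit_identical(self):
        from pulmodpm import load_config, run_scenario

        cfg = load_config({
            "species": "human", "duration_s": 20.0,
            "control": {"fixed_ve_l_min": 7.0, "fixed_q_l_min": 6.5},
        })
        a = run_scenario(cfg)
        b = run_scenario(cfg)
        for key in a.channels:
            np.testing.assert_array_equal(a[key], b[key])
        np.testing.assert_array_equal(a.time_s, b.time_s)


class TestClosedLoopRest:
    def test_resting_room_air_lands_in_physiologic_envelope(self, human):
        """Closed-loop rest with default gains: P_aO2 85-105 mmHg, P_aCO2
        35-45 mmHg, VE 5-8 L/min."""
        summary, _ = steady_state(human, {"work_w": 0.0})
        assert 85.0 <= summary["p_a_o2_mmhg"] <= 105.0
        assert 35.0 <= summary["p_a_co2_mmhg"] <= 45.0
        assert 5.0 <= summary["ve_l_min"] <= 8.0
        assert summary["sao2"] > 0.94


class TestWholeBodyBalance:
    def test_lung_uptake_equals_tissue_consumption_at_steady_state(self):
        lung = make_fixture_lung(2, symmetric=True)
        settings = SolverSettings(ss_rel_change=1e-4, dt_s=0.02)
        _, state = steady_state(
            lung, {"fixed_ve_l_min": 6.5, "fixed_q_l_min": 6.5}, settings=settings
        )
        sim = LungSimulator(lung, fixed_ve_l_min=6.5, fixed_q_l_min=6.5,
                            settings=settings)
        uptake = np.zeros(2)
        t = 0.0
        for _ in range(10):
            diag = sim.run_breath(state)
            uptake += diag.transferred_to_blood
            t += diag.duration_s
        vo2_uptake = uptake[0] / t * 60.0 / 1000.0  # L/min
        vco2_out = -uptake[1] / t * 60.0 / 1000.0
        assert vo2_uptake == pytest.approx(0.3, rel=0.01)
        assert vco2_out == pytest.approx(0.255, rel=0.01)
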