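"""Exchange primitives against closed-form and stiff-integrator oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pulmodpm.blood import BloodChemistry
from pulmodpm.constants import RT_BTPS
from pulmodpm.errors import DomainError, InvalidStateError
from pulmodpm.gas_transport import (
    CapillaryTrain,
    airway_step,
    alveolar_step,
    capillary_rate_coefficients,
    capillary_step,
    dl_oxygen,
    mix_arterial,
)


class TestAirwayStep:
    def test_zero_flow_leaves_concentration(self):
        assert airway_step(50.0, 0.4, 0.9, 0.0, 0.01) == 0.4

    def test_equilibrium_is_fixed_point(self):
        assert airway_step(50.0, 0.4, 0.4, 123.0, 0.01) == pytest.approx(0.4)

    def test_single_step_value(self):
        # V=100 ml, flow=100 ml/s, dt=10 ms: C = (0 + 0.01*1)/(1.01)
        assert airway_step(100.0, 0.0, 1.0, 100.0, 0.01) == pytest.approx(0.01 / 1.01)

    def test_bounded_between_old_and_inlet(self):
        c = airway_step(10.0, 0.2, 0.8, 500.0, 0.05)
        assert 0.2 < c < 0.8

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidStateError):
            airway_step(10.0, -0.1, 0.5, 10.0, 0.01)

    def test_washout_matches_analytic_with_order_one_convergence(self):
        """Backward Euler vs C(t) = 1 - exp(-t*flow/V): observed order >= 1."""
        vol, flow, t_end = 100.0, 100.0, 0.2
        exact = 1.0 - np.exp(-t_end * flow / vol)

        def run(dt):
            c, n = 0.0, int(round(t_end / dt))
            for _ in range(n):
                c = airway_step(vol, c, 1.0, flow, dt)
            return c

        e1 = abs(run(0.01) - exact)
        e2 = abs(run(0.005) - exact)
        order = np.log2(e1 / e2)
        assert order >= 0.9
        assert e1 < 0.01


class TestAlveolarStep:
    def test_exhale_with_no_diffusion_keeps_concentration(self):
        v, c, _ = alveolar_step(1000.0, 0.1, "exhale", None, 50.0, 40.0, 0.0, 1.0, 0.01)
        assert c == pytest.approx(0.1, rel=1e-12)
        assert v == pytest.approx(999.5)

    def test_diffusion_equilibrium_is_fixed_point(self):
        c0 = 100.0 / RT_BTPS
        _, c, flux = alveolar_step(1000.0, c0, "inhale", c0, 0.0, 100.0, 40.0, 1.0, 0.01)
        assert c == pytest.approx(c0, rel=1e-12)
        assert flux == pytest.approx(0.0, abs=1e-15)

    def test_inhale_without_diffusion_is_pure_dilution(self):
        v0, c0, cin, q, dt = 1000.0, 0.05, 0.15, 400.0, 0.01
        v, c, _ = alveolar_step(v0, c0, "inhale", cin, q, 0.0, 0.0, 1.0, dt)
        # conservative mixing: (V0*C0 + q*dt*Cin) / (V0 + q*dt)
        assert c == pytest.approx((v0 * c0 + q * dt * cin) / (v0 + q * dt), rel=1e-12)

    def test_volume_underflow_raises(self):
        with pytest.raises(InvalidStateError):
            alveolar_step(10.0, 0.1, "exhale", None, 2000.0, 40.0, 10.0, 1.0, 0.01)

    def test_against_stiff_integrator(self):
        """Repeated implicit steps vs Radau solution of the inhalation ODE."""
        v0, c0, c_in, flow = 2000.0, 90.0 / RT_BTPS, 140.0 / RT_BTPS, 300.0
        p_c, dl, f_i, t_end = 45.0, 35.0, 0.3, 0.8

        def rhs(t, y):
            v = v0 + flow * t
            g = f_i * dl / 60.0
            return [(flow * (c_in - y[0]) - g * (RT_BTPS * y[0] - p_c) / 1.0) / v]

        sol = solve_ivp(rhs, (0, t_end), [c0], method="Radau", rtol=1e-10, atol=1e-14)
        dt, v, c = 2e-4, v0, c0
        for _ in range(int(round(t_end / dt))):
            v, c, _ = alveolar_step(v, c, "inhale", c_in, flow, p_c, dl, f_i, dt)
        assert c == pytest.approx(sol.y[0, -1], rel=2e-4)


class TestDlOxygen:
    @pytest.mark.parametrize(
        "p, w, expected",
        [
            (0.0, 0.0, 76.0),
            (100.0, 0.0, -78.0 + 30.0 + 76.0),
            (100.0, 150.0, -78.0 + (0.3 + 150 / 833) * 100 + 76 + 25.0),
        ],
    )
    def test_quadratic_values(self, p, w, expected):
        assert dl_oxygen(p, w) == pytest.approx(expected, rel=1e-12)

    def test_floor_applies_where_quadratic_is_negative(self):
        assert dl_oxygen(200.0, 0.0, p_clamp_mmhg=None) == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            dl_oxygen(-1.0, 0.0)
        with pytest.raises(DomainError):
            dl_oxygen(50.0, -10.0)


class TestCapillaryTrain:
    def _train(self, n=6, chem=None, q=5000.0, v_cap=75.0, f_k=0.2):
        chem = chem or BloodChemistry()
        return CapillaryTrain(
            n=n, q_c_ml_min=q, v_capillary_ml=v_cap, f_k=f_k, gas="O2",
            chemistry=chem,
            contents=np.full(n, chem.o2_content(40.0)),
        )

    def test_no_exchange_outlet_equals_inlet_at_steady_state(self):
        train = self._train()
        inlet = train.chemistry.o2_content(40.0)
        for _ in range(500):
            capillary_step(train, inlet, 100.0, 0.0, 0.05)
        assert train.outlet_content == pytest.approx(inlet, rel=1e-12)

    def test_linear_chemistry_matches_geometric_recursion(self):
        """Steady state vs C_i = (C_{i-1} + a*beta*P_alv)/(1+a), the
        closed-form serial-compartment solution under linear chemistry."""
        beta = 0.003
        chem = BloodChemistry(linear_o2_beta=beta)
        n, q, v_cap, f_k, dl, p_alv = 7, 4000.0, 75.0, 0.25, 30.0, 100.0
        train = CapillaryTrain(
            n=n, q_c_ml_min=q, v_capillary_ml=v_cap, f_k=f_k, gas="O2",
            chemistry=chem, contents=np.full(n, beta * 40.0),
        )
        inlet = beta * 40.0
        for _ in range(4000):
            capillary_step(train, inlet, p_alv, dl, 0.05)
        a = f_k * dl / (n * q * beta)
        expected, c = [], inlet
        for _ in range(n):
            c = (c + a * beta * p_alv) / (1.0 + a)
            expected.append(c)
        np.testing.assert_allclose(train.contents, expected, rtol=1e-10)

    def test_large_dl_outlet_approaches_alveolar_pressure(self):
        train = self._train()
        inlet = train.chemistry.o2_content(40.0)
        for _ in range(800):
            capillary_step(train, inlet, 100.0, 5000.0, 0.05)
        assert abs(train.outlet_pressure - 100.0) < 0.1

    def test_combined_rate_coefficients_equal_per_division_composition(self):
        """The collapsed per-division rates must equal the composition of
        the division volume V_cap*f_k/n with the division flow and the
        per-division membrane share f_k*D_L/n (algebraic identity)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            q_tot, f_q = rng.uniform(1e3, 3e4), rng.uniform(0.01, 1.0)
            v_cap, f_k = rng.uniform(20, 150), rng.uniform(0.01, 1.0)
            q_c = q_tot * f_q  # segmental perfusion share of cardiac output
            v_c_div = v_cap * f_k / n  # serial division volume
            k_flow, k_diff = capillary_rate_coefficients(n, q_c, v_cap, f_k)
            assert k_flow == pytest.approx(q_c / 60.0 / v_c_div, rel=1e-12)
            assert k_diff == pytest.approx((f_k / n) / v_c_div / 60.0, rel=1e-12)

    def test_invalid_train_parameters_rejected(self):
        with pytest.raises(InvalidStateError):
            CapillaryTrain(n=0, q_c_ml_min=100.0, v_capillary_ml=75.0, f_k=0.1)
        with pytest.raises(InvalidStateError):
            CapillaryTrain(n=5, q_c_ml_min=-1.0, v_capillary_ml=75.0, f_k=0.1)


class TestMixArterial:
    def test_no_shunt_is_flow_weighted_mean(self):
        c = np.array([0.18, 0.20, 0.22])
        w = np.array([0.5, 0.3, 0.2])
        assert mix_arterial(c, w, 0.10, 0.0) == pytest.approx((c * w).sum())

    def test_full_shunt_returns_venous(self):
        assert mix_arterial([0.2, 0.2], [0.5, 0.5], 0.15, 1.0) == pytest.approx(0.15)

    def test_partial_shunt_weighted_average(self):
        # 0.85*0.20 + 0.15*0.15
        assert mix_arterial([0.2, 0.2], [0.6, 0.4], 0.15, 0.15) == pytest.approx(0.1925)

    def test_shunt_domain_and_weight_mismatch(self):
        with pytest.raises(DomainError):
            mix_arterial([0.2], [1.0], 0.1, 1.5)
        with pytest.raises(InvalidStateError):
            mix_arterial([0.2, 0.3], [1.0], 0.1, 0.0)
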