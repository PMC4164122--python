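"""Injury-to-impairment mapping and the calibration fitters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulmodpm import generate_calibration_data, make_fixture_lung
from pulmodpm.damage import (
    CalibrationPoint,
    DamageState,
    damage_from_weight_change,
    dl_reduction_from_shunt,
    fit_damage_line,
    fit_shunt_dl,
    shunt_from_dl_reduction,
    weight_gain_pattern,
)
from pulmodpm.errors import DomainError, FitError


class TestShuntDlCoupling:
    @pytest.mark.parametrize("x, expected", [(0.0, 0.0), (0.4, 0.06), (1.0, 0.15)])
    def test_linear_coupling(self, x, expected):
        assert shunt_from_dl_reduction(x) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            shunt_from_dl_reduction(1.2)
        with pytest.raises(DomainError):
            shunt_from_dl_reduction(-0.1)

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(0.0, 1.0))
    def test_round_trip(self, x):
        assert dl_reduction_from_shunt(shunt_from_dl_reduction(x)) == pytest.approx(
            x, abs=1e-12
        )


class TestDamageFromWeightChange:
    def test_no_weight_gain_is_healthy(self):
        d = damage_from_weight_change(np.zeros(5), np.full(5, 0.2), k_w=0.4,
                                      baseline_shunt=0.02)
        assert d.shunt == pytest.approx(0.02)
        assert np.all(d.dl_reduction == 0.0)

    def test_uniform_damage_inverts_coupling(self):
        # k_w * dW = 0.15 drives every segment to complete D_L loss
        dw = np.full(4, 0.15 / 0.4)
        d = damage_from_weight_change(dw, np.full(4, 0.25), k_w=0.4, baseline_shunt=0.0)
        assert d.shunt == pytest.approx(0.15)
        np.testing.assert_allclose(d.dl_reduction, 1.0)

    def test_regional_matches_uniform_global_shunt(self, human):
        """38.1% weight gain confined to the right lung (52.5% of volume)
        yields the same volume-weighted mean and hence the same global shunt
        as 20% uniform weight gain."""
        vol = np.array([s.volume_fraction for s in human.segments])
        dw_reg = weight_gain_pattern(human, {"region": "right", "dw": 0.381})
        dw_uni = weight_gain_pattern(human, {"uniform": 0.20})
        mean_reg = (dw_reg * vol).sum()
        assert mean_reg == pytest.approx(0.381 * 0.525, rel=1e-9)
        assert mean_reg == pytest.approx(0.20, abs=2e-3)
        d_reg = damage_from_weight_change(dw_reg, vol, k_w=0.375)
        d_uni = damage_from_weight_change(dw_uni, vol, k_w=0.375)
        assert d_reg.shunt == pytest.approx(d_uni.shunt, abs=1e-3)
        # but the regional pattern concentrates the diffusion impairment
        assert d_reg.dl_reduction.max() > d_uni.dl_reduction.max()
        assert d_reg.dl_reduction.min() == 0.0

    def test_shunt_saturates_with_warning(self):
        with pytest.warns(UserWarning):
            d = damage_from_weight_change(np.full(3, 5.0), np.full(3, 1 / 3), k_w=1.0)
        assert d.shunt == 1.0

    def test_per_segment_pattern(self, human):
        dw = weight_gain_pattern(human, {"per_segment": {19: 0.3, 25: 0.1}})
        ids = [s.id for s in human.segments]
        assert dw[ids.index(19)] == 0.3
        assert dw[ids.index(25)] == 0.1
        assert dw.sum() == pytest.approx(0.4)


class TestFitDamageLine:
    def _points(self, x, y):
        return [CalibrationPoint("dl_reduction", xi, yi) for xi, yi in zip(x, y)]

    def test_exact_line_recovered(self):
        x = np.linspace(0.1, 1.0, 6)
        slope, intercept, r2 = fit_damage_line(self._points(x, 0.15 * x))
        assert slope == pytest.approx(0.15, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(FitError):
            fit_damage_line(self._points([0.5, 0.5, 0.5], [0.1, 0.2, 0.3]))
        with pytest.raises(FitError):
            fit_damage_line(self._points([0.5], [0.1]))

    def test_pinned_intercept(self):
        x = np.linspace(0.1, 1.0, 8)
        slope, intercept, _ = fit_damage_line(
            self._points(x, 0.02 + 0.15 * x), pin_intercept=0.02
        )
        assert intercept == 0.02
        assert slope == pytest.approx(0.15, abs=1e-12)

    def test_noisy_synthetic_points_recover_slope(self):
        df = generate_calibration_data(slope=0.15, noise_sigma=0.01, n=20, seed=42)
        pts = self._points(df["x_value"], df["shunt"])
        slope, _, r2 = fit_damage_line(pts)
        assert 0.13 <= slope <= 0.17
        assert r2 > 0.8


class TestFitShuntDl:
    """Fast checks through an injected analytic predictor; full-simulation
    recovery is exercised in the acceptance suite."""

    @staticmethod
    def _toy_predictor(work, shunt, dl_red):
        # smooth, monotone-decreasing in both damage parameters
        return 100.0 - 150.0 * shunt - 40.0 * dl_red - 0.05 * work * (1 + dl_red)

    def test_recovers_planted_parameters(self, human):
        truth = (0.12, 0.55)
        works = [0.0, 75.0, 150.0]
        data = [(w, self._toy_predictor(w, *truth)) for w in works]
        res = fit_shunt_dl({"oa": data}, human, predictor=self._toy_predictor)
        s, r, resid = res["oa"]
        assert s == pytest.approx(truth[0], abs=1e-3)
        assert r == pytest.approx(truth[1], abs=1e-3)
        assert resid < 1e-8

    def test_healthy_data_yields_zero_damage(self, human):
        works = [0.0, 100.0]
        data = [(w, self._toy_predictor(w, 0.0, 0.0)) for w in works]
        res = fit_shunt_dl({"healthy": data}, human, predictor=self._toy_predictor,
                           x0=(0.02, 0.05))
        s, r, _ = res["healthy"]
        assert s < 0.01 and r < 0.02

    def test_too_few_observations_rejected(self, human):
        with pytest.raises(FitError):
            fit_shunt_dl({"x": [(0.0, 90.0)]}, human, predictor=self._toy_predictor)


def test_damage_state_validation():
    with pytest.raises(DomainError):
        DamageState(weight_gain=[-0.1], dl_reduction=[0.0], shunt=0.0)
    with pytest.raises(DomainError):
        DamageState(weight_gain=[0.0], dl_reduction=[1.4], shunt=0.0)
    with pytest.raises(DomainError):
        DamageState(weight_gain=[0.0], dl_reduction=[0.0], shunt=1.2)
    h = DamageState.healthy(3, baseline_shunt=0.02)
    assert h.shunt == 0.02
    assert np.all(h.dl_reduction == 0.0)
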