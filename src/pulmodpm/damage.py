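"""Lung-injury model: fluid infiltration -> diffusing-capacity loss + shunt.

Injury by blast, blunt trauma or permeability edema (oleic acid) is
quantified as fractional lung weight gain dW from fluid/blood infiltration.
Infiltration impairs gas exchange through two coupled parameters:

* a fractional reduction of the O2 diffusing capacity D_L, applied per
  segment, and
* a global venous-admixture shunt, applied at arterial recombination.

Calibration against animal exercise data ties the two together linearly,

    shunt ~= 0.15 * D_L_reduction

and a second (uncertain, config-exposed) linear coefficient k_w maps weight
gain to damage-induced shunt.  With both relations, a regional weight-gain
map determines per-segment D_L reduction and one whole-lung shunt; uniform
and regional damage with the same volume-weighted mean dW produce the same
global shunt, but different regional diffusion impairment.

Damage is static during a simulation (injury at steady state, simulated
timescales shorter than recovery).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .anatomy import LungModel
from .errors import DomainError, FitError

__all__ = [
    "DL_SHUNT_SLOPE",
    "K_W_DEFAULT",
    "DamageState",
    "CalibrationPoint",
    "shunt_from_dl_reduction",
    "dl_reduction_from_shunt",
    "damage_from_weight_change",
    "weight_gain_pattern",
    "fit_damage_line",
    "fit_shunt_dl",
]

#: Calibrated coupling between shunt and D_L reduction (dimensionless).
DL_SHUNT_SLOPE = 0.15

#: Default shunt increment per unit fractional lung weight gain.  The source
#: calibration never prints this slope; the default is a synthetic
#: reconstruction and quantitative work should set it explicitly.
K_W_DEFAULT = 0.375


def shunt_from_dl_reduction(dl_reduction):
    """Shunt fraction implied by a fractional D_L reduction (0.15 coupling)."""
    x = np.asarray(dl_reduction, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise DomainError(f"D_L reduction must be in [0, 1], got {dl_reduction}")
    out = np.clip(DL_SHUNT_SLOPE * x, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def dl_reduction_from_shunt(shunt):
    """Inverse of the shunt/D_L coupling (no clipping of the input)."""
    x = np.asarray(shunt, dtype=float)
    if np.any(x < 0):
        raise DomainError("shunt must be non-negative")
    out = x / DL_SHUNT_SLOPE
    return float(out) if out.ndim == 0 else out


@dataclass
class DamageState:
    """Per-segment injury state plus the derived exchange impairments.

    Arrays are aligned with ``LungModel.segments`` order.  ``shunt`` is the
    total arterial admixture fraction including the healthy baseline.
    """

    weight_gain: np.ndarray
    dl_reduction: np.ndarray
    shunt: float

    def __post_init__(self) -> None:
        self.weight_gain = np.asarray(self.weight_gain, dtype=float)
        self.dl_reduction = np.asarray(self.dl_reduction, dtype=float)
        if np.any(self.weight_gain < 0):
            raise DomainError("weight gain must be non-negative")
        if np.any(self.dl_reduction < 0) or np.any(self.dl_reduction > 1):
            raise DomainError("D_L reduction must be in [0, 1]")
        if not (0.0 <= self.shunt <= 1.0):
            raise DomainError("shunt must be in [0, 1]")

    @classmethod
    def healthy(cls, n_segments: int, baseline_shunt: float = 0.02) -> "DamageState":
        z = np.zeros(n_segments)
        return cls(weight_gain=z, dl_reduction=z.copy(), shunt=baseline_shunt)

    @classmethod
    def uniform(cls, n_segments: int, shunt: float, dl_reduction: float) -> "DamageState":
        """Direct uniform impairment (used by the calibration fits)."""
        return cls(
            weight_gain=np.zeros(n_segments),
            dl_reduction=np.full(n_segments, float(dl_reduction)),
            shunt=float(shunt),
        )


def weight_gain_pattern(model: LungModel, pattern) -> np.ndarray:
    """Expand a damage-pattern spec into a per-segment dW array.

    Accepted forms: a scalar (uniform), ``{"uniform": dw}``,
    ``{"region": "left"|"right", "dw": dw}``, or
    ``{"per_segment": {segment_id: dw}}``.
    """
    n = len(model.segments)
    if np.isscalar(pattern):
        return np.full(n, float(pattern))
    if "uniform" in pattern:
        return np.full(n, float(pattern["uniform"]))
    if "region" in pattern:
        side = pattern["region"]
        ids = set(model.segments_on_side(side))
        if not ids:
            raise DomainError(f"no segments on side {side!r}")
        return np.array(
            [float(pattern["dw"]) if s.id in ids else 0.0 for s in model.segments]
        )
    if "per_segment" in pattern:
        per = {int(k): float(v) for k, v in pattern["per_segment"].items()}
        return np.array([per.get(s.id, 0.0) for s in model.segments])
    raise DomainError(f"unrecognized damage pattern {pattern!r}")


def damage_from_weight_change(
    weight_gain,
    volume_fractions,
    k_w: float = K_W_DEFAULT,
    baseline_shunt: float = 0.02,
) -> DamageState:
    """Map per-segment fractional weight gain to a DamageState.

    The damage-induced global shunt is ``k_w`` times the volume-weighted mean
    weight gain (added to the healthy baseline); the per-segment D_L
    reduction inverts the 0.15 shunt/D_L coupling regionally,
    ``k_w * dW_k / 0.15``, clipped to [0, 1].  Undamaged segments are left
    untouched.
    """
    dw = np.asarray(weight_gain, dtype=float)
    vol = np.asarray(volume_fractions, dtype=float)
    if np.any(dw < 0):
        raise DomainError("weight gain must be non-negative")
    if k_w <= 0:
        raise DomainError("k_w must be positive")
    mean_dw = float((dw * vol).sum() / vol.sum())
    shunt = baseline_shunt + k_w * mean_dw
    if shunt > 1.0:
        warnings.warn("damage shunt exceeds 1; saturating", stacklevel=2)
        shunt = 1.0
    dl_red = np.clip(k_w * dw / DL_SHUNT_SLOPE, 0.0, 1.0)
    return DamageState(weight_gain=dw, dl_reduction=dl_red, shunt=shunt)


# -- calibration ------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationPoint:
    """One figure-style calibration observation."""

    x_kind: str  # "dl_reduction" | "weight_gain"
    x_value: float
    shunt: float
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.x_value) or not np.isfinite(self.shunt):
            raise DomainError("calibration values must be finite")
        if self.x_value < 0 or self.shunt < 0:
            raise DomainError("calibration values must be non-negative")


def fit_damage_line(points, pin_intercept: float | None = None):
    """Ordinary least squares through calibration points.

    Returns ``(slope, intercept, r_squared)``.  With ``pin_intercept`` set,
    only the slope is fitted through the pinned intercept.
    """
    pts = list(points)
    if len(pts) < 2:
        raise FitError("need at least 2 calibration points")
    x = np.array([p.x_value for p in pts])
    y = np.array([p.shunt for p in pts])
    if np.ptp(x) == 0:
        raise FitError("degenerate calibration data: all x values equal")
    if pin_intercept is not None:
        yc = y - pin_intercept
        slope = float((x * yc).sum() / (x * x).sum())
        resid = yc - slope * x
        ss_tot = float(((yc - yc.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
        return slope, float(pin_intercept), r2
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_shunt_dl(
    curves: dict,
    model: LungModel,
    environment=None,
    solver=None,
    x0=(0.05, 0.3),
    predictor=None,
):
    """Fit (shunt, D_L reduction) per condition from arterial-O2/workload data.

    ``curves`` maps a condition label to a sequence of ``(workload_W,
    arterial_PO2_mmHg)`` observations.  For each condition the uniform
    damage pair minimizing the least-squares error between modelled and
    observed steady-state arterial PO2 is returned as
    ``{label: (shunt, dl_reduction, residual_sum_sq)}``.

    ``predictor(workload, shunt, dl_reduction) -> P_a_O2`` may be injected
    (mainly for testing); by default a closed-loop steady-state simulation
    of ``model`` is used.
    """
    from . import simulate  # local import; simulate depends on this module's types

    if predictor is None:
        predictor = simulate.make_steady_state_predictor(
            model, environment=environment, solver=solver
        )

    results = {}
    for label, obs in curves.items():
        obs = list(obs)
        if len(obs) < 2:
            raise FitError(f"condition {label!r}: need >= 2 observations")
        works = np.array([o[0] for o in obs], dtype=float)
        target = np.array([o[1] for o in obs], dtype=float)

        def residuals(theta):
            s, r = float(np.clip(theta[0], 0.0, 1.0)), float(np.clip(theta[1], 0.0, 1.0))
            pred = np.array([predictor(w, s, r) for w in works])
            return pred - target

        try:
            sol = optimize.least_squares(
                residuals,
                x0=np.asarray(x0, dtype=float),
                bounds=([0.0, 0.0], [1.0, 1.0]),
                diff_step=0.02,
                xtol=1e-4,
                ftol=1e-6,
                gtol=1e-8,
            )
        except Exception as exc:  # pragma: no cover - optimizer internals
            raise FitError(f"condition {label!r}: optimizer failure: {exc}") from exc
        if not sol.success:
            raise FitError(f"condition {label!r}: fit did not converge: {sol.message}")
        results[label] = (float(sol.x[0]), float(sol.x[1]), float(2.0 * sol.cost))
    return results
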