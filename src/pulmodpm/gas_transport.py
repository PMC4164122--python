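"""Airway, alveolar and capillary gas-exchange primitives.

All transport updates are backward-Euler (implicit) in the transported
concentration, which makes every step unconditionally stable and bounded
between the old value and the inlet value.  The alveolar update is written
in conservative form d(VC)/dt so that breath-level gas accounting telescopes
exactly through the airway chain.

Units follow ``pulmodpm.constants``: concentrations are ml STPD gas per ml,
pressures mmHg, diffusing capacities ml/(mmHg*min), flows ml/s inside the
steppers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blood import BloodChemistry, DEFAULT_CHEMISTRY
from .constants import RT_BTPS, SECONDS_PER_MINUTE
from .errors import DomainError, InvalidStateError

__all__ = [
    "GasSpecies",
    "AlveolarCompartment",
    "CapillaryTrain",
    "airway_step",
    "alveolar_step",
    "dl_oxygen",
    "capillary_step",
    "capillary_rate_coefficients",
    "mix_arterial",
    "o2_saturation",
    "o2_content",
    "content_to_pressure",
]

DL_O2_FLOOR = 1.0  # ml/(mmHg*min); the quadratic D_L relation can go negative


@dataclass(frozen=True)
class GasSpecies:
    """Descriptor for a transported gas."""

    name: str  # "O2" | "CO2"
    solubility: float  # dissolved beta, ml gas/(ml blood * mmHg)
    rt_conversion: float = RT_BTPS  # mmHg per (ml STPD / ml BTPS)
    membrane_dl: float = 40.0  # ml/(mmHg*min), healthy whole-lung reference

    def __post_init__(self) -> None:
        if self.solubility <= 0 or self.rt_conversion <= 0:
            raise InvalidStateError("gas solubility and RT conversion must be positive")


O2 = GasSpecies("O2", solubility=3.0e-5, membrane_dl=40.0)
CO2 = GasSpecies("CO2", solubility=6.7e-4, membrane_dl=800.0)


# -- airway -----------------------------------------------------------------


def airway_step(volume_ml, c_old, c_in, flow_ml_s, dt_s):
    """One implicit update of a rigid well-mixed airway compartment.

    V dC/dt = flow * (C_in - C), discretized backward Euler:

        C_new = (C_old + r * C_in) / (1 + r),   r = flow*dt/V

    ``c_in`` is the parent concentration on inhalation and the (mixed)
    daughter concentration on exhalation; the caller picks the direction.
    Accepts scalars or aligned arrays.
    """
    c_old = np.asarray(c_old, dtype=float)
    if dt_s <= 0:
        raise DomainError("dt must be positive")
    if np.any(np.asarray(flow_ml_s) < 0):
        raise DomainError("flow magnitude must be non-negative")
    if np.any(c_old < 0) or np.any(np.asarray(c_in) < 0):
        raise InvalidStateError("negative gas concentration")
    r = np.asarray(flow_ml_s, dtype=float) * dt_s / np.asarray(volume_ml, dtype=float)
    out = (c_old + r * np.asarray(c_in, dtype=float)) / (1.0 + r)
    return float(out) if out.ndim == 0 else out


# -- alveolar ---------------------------------------------------------------


@dataclass
class AlveolarCompartment:
    """State of one variable-volume alveolar gas space (one segment).

    Concentrations are per gas: index 0 = O2, 1 = CO2.  ``f_i`` is the
    membrane-area fraction of the segment (equal to its volume fraction).
    """

    volume_ml: float
    concentration: np.ndarray  # shape (2,), ml STPD / ml
    f_i: float
    residual_floor_ml: float = 1.0

    @property
    def partial_pressure(self) -> np.ndarray:
        return self.concentration * RT_BTPS


def alveolar_step(
    v_alv_ml,
    c_alv,
    phase: str,
    c_in,
    flow_ml_s,
    p_c_mmhg,
    dl_ml_mmhg_min,
    f_i,
    dt_s,
    residual_floor_ml: float = 1.0,
):
    """Advance an alveolar compartment over ``dt_s``.

    Inhalation:  d(VC)/dt = flow * C_in - f_i*D_L/60 * (RT*C - P_c),  dV/dt = +flow
    Exhalation:  d(VC)/dt = -flow * C   - f_i*D_L/60 * (RT*C - P_c),  dV/dt = -flow

    The diffusion term drives the alveolar partial pressure RT*C toward the
    capillary pressure ``p_c_mmhg``.  Discretization is backward Euler on C
    with the new volume, conservative in the stored gas amount V*C.

    Returns ``(v_new, c_new, transferred_ml)`` where ``transferred_ml`` is
    the gas volume (STPD, per gas) moved into the blood during the step.
    """
    c_alv = np.asarray(c_alv, dtype=float)
    p_c = np.asarray(p_c_mmhg, dtype=float)
    g = np.asarray(f_i, dtype=float) * np.asarray(dl_ml_mmhg_min, dtype=float) / SECONDS_PER_MINUTE
    if phase == "inhale":
        v_new = np.asarray(v_alv_ml, dtype=float) + np.asarray(flow_ml_s, dtype=float) * dt_s
        num = v_alv_ml * c_alv + dt_s * (np.asarray(flow_ml_s, dtype=float) * np.asarray(c_in, dtype=float) + g * p_c)
        den = v_new + dt_s * g * RT_BTPS
    elif phase == "exhale":
        v_new = np.asarray(v_alv_ml, dtype=float) - np.asarray(flow_ml_s, dtype=float) * dt_s
        if np.any(v_new < residual_floor_ml):
            raise SolverVolumeError(v_new)
        num = v_alv_ml * c_alv + dt_s * g * p_c
        den = v_new + dt_s * (np.asarray(flow_ml_s, dtype=float) + g * RT_BTPS)
    else:
        raise DomainError(f"phase must be 'inhale' or 'exhale', got {phase!r}")
    c_new = num / den
    transferred = dt_s * g * (RT_BTPS * c_new - p_c)
    return v_new, c_new, transferred


class SolverVolumeError(InvalidStateError):
    """Exhalation drove an alveolar compartment below its residual floor."""

    def __init__(self, volumes) -> None:
        bad = np.atleast_1d(np.asarray(volumes))
        idx = list(np.nonzero(~(bad > 0))[0]) or "unknown"
        super().__init__(f"alveolar volume underflow (segment index {idx}, volumes {bad})")


# -- diffusing capacity -----------------------------------------------------


DL_O2_P_VALID_MAX = 110.0  # mmHg; evaluation clamp for the empirical relation


def dl_oxygen(p_alv_o2_mmhg, work_w=0.0, floor: float = DL_O2_FLOOR,
              p_clamp_mmhg: float = DL_O2_P_VALID_MAX):
    """Whole-lung O2 diffusing capacity as a function of alveolar PO2 and workload.

    D_L,O2 = -0.0078*P^2 + (0.3 + Work/833)*P + 76 + Work/6   [ml/(mmHg*min)]

    The downward-opening quadratic is an empirical fit over the physiologic
    alveolar range and becomes negative when extrapolated to high PO2; the
    evaluation pressure is therefore clamped at ``p_clamp_mmhg`` (beyond
    which D_L is held at its boundary value) and the result floored at
    ``floor`` to keep the exchange equations well-posed.  Pass
    ``p_clamp_mmhg=None`` for the raw quadratic.
    """
    p = np.asarray(p_alv_o2_mmhg, dtype=float)
    w = np.asarray(work_w, dtype=float)
    if np.any(p < 0) or np.any(w < 0):
        raise DomainError("alveolar PO2 and workload must be non-negative")
    if p_clamp_mmhg is not None:
        p = np.minimum(p, p_clamp_mmhg)
    dl = -0.0078 * p**2 + (0.3 + w / 833.0) * p + 76.0 + w / 6.0
    out = np.maximum(dl, floor)
    return float(out) if out.ndim == 0 else out


# -- capillary --------------------------------------------------------------


def capillary_rate_coefficients(n, q_c_ml_min, v_capillary_ml, f_k):
    """Per-division rate coefficients of the serial capillary train.

    Composing the division volume V_c = V_capillary*f_k/n with the division
    flow Q_c gives the transport rate; the diffusion rate uses the per-
    division membrane share f_k*D_L/n over the same volume, in which f_k and
    n cancel:

        k_flow = n * Q_c / (V_capillary * f_k)          [1/s]
        k_diff = D_L / V_capillary / 60  (per unit D_L) [1/(s * ml/mmHg/min)]

    Returns ``(k_flow_per_s, k_diff_per_dl)``.
    """
    k_flow = n * (q_c_ml_min / SECONDS_PER_MINUTE) / (v_capillary_ml * f_k)
    k_diff_per_dl = 1.0 / (v_capillary_ml * SECONDS_PER_MINUTE)
    return k_flow, k_diff_per_dl


@dataclass
class CapillaryTrain:
    """Serial capillary divisions of one segment, for one gas.

    ``contents`` holds the per-division blood gas content inlet-to-outlet;
    pressures are recovered through the dissociation curve on demand.
    """

    n: int
    q_c_ml_min: float  # Q_Tot * f_Q,k actually perfusing this train
    v_capillary_ml: float  # whole-lung capillary volume
    f_k: float  # segment volume fraction
    gas: str = "O2"
    chemistry: BloodChemistry = field(default_factory=BloodChemistry)
    contents: np.ndarray | None = None
    pressures: np.ndarray | None = None  # warm-start cache for the solver

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidStateError("capillary train needs n >= 1 divisions")
        if self.q_c_ml_min <= 0 or self.v_capillary_ml <= 0 or self.f_k <= 0:
            raise InvalidStateError("capillary train flows and volumes must be positive")
        if self.contents is None:
            p0 = 40.0
            self.contents = np.full(self.n, self.chemistry.content(self.gas, p0))
        self.contents = np.asarray(self.contents, dtype=float)
        if np.any(self.contents < 0):
            raise InvalidStateError("negative capillary contents")
        if self.pressures is None:
            self.pressures = np.asarray(
                self.chemistry.pressure_from_content(self.gas, self.contents), dtype=float
            ).reshape(self.n)

    @property
    def division_volume_ml(self) -> float:
        return self.v_capillary_ml * self.f_k / self.n

    @property
    def outlet_content(self) -> float:
        return float(self.contents[-1])

    @property
    def outlet_pressure(self) -> float:
        return float(self.chemistry.pressure_from_content(self.gas, self.contents[-1]))


def _implicit_division_update(
    chem: BloodChemistry,
    gas: str,
    c_old,
    c_in,
    p_guess,
    p_alv,
    a_flow,
    a_diff,
    tol: float = 1e-9,
    max_iter: int = 60,
):
    """Solve the backward-Euler division update in pressure space.

    g(P) = C(P)*(1 + a_flow) - c_old - a_flow*c_in + a_diff*(P - p_alv) = 0

    with a_flow = dt*k_flow and a_diff = dt*k_diff*D_L.  g is strictly
    increasing, so Newton with a bisection safeguard always converges.
    Vectorized over aligned arrays; returns (P_new, C_new).
    """
    c_old = np.asarray(c_old, dtype=float)
    lin = chem.linear_coeffs(gas)
    if lin is not None:
        a, b = lin
        num = c_old + a_flow * np.asarray(c_in, dtype=float) + a_diff * np.asarray(p_alv, dtype=float) - a * (1.0 + a_flow)
        p_new = np.maximum(num / (b * (1.0 + a_flow) + a_diff), 0.0)
        return p_new, chem.content(gas, p_new)
    # inlined Hill curve (hot path: called per division per solver substep)
    cap, beta = chem.o2_capacity_ml_ml, chem.beta_o2
    n_h, p50 = chem.hill_n, chem.p50_mmhg
    c_in = np.asarray(c_in, dtype=float)
    p_alv = np.asarray(p_alv, dtype=float)
    p = np.maximum(np.asarray(p_guess, dtype=float), 1e-9)
    lo = np.zeros_like(c_old + 0.0 * p)
    hi = np.full_like(lo, 1500.0)
    p = np.broadcast_to(p, lo.shape).copy()
    for _ in range(max_iter):
        r = (p / p50) ** n_h
        one_r = 1.0 + r
        c = cap * r / one_r + beta * p
        g = c * (1.0 + a_flow) - c_old - a_flow * c_in + a_diff * (p - p_alv)
        hi = np.where(g > 0, p, hi)
        lo = np.where(g < 0, p, lo)
        dg = (cap * n_h * r / (np.maximum(p, 1e-12) * one_r * one_r) + beta) * (1.0 + a_flow) + a_diff
        step = g / dg
        if np.all(np.abs(step) < tol * np.maximum(1.0, p)):
            p = np.maximum(p - step, 0.0)
            break
        p_new = p - step
        bad = (p_new < lo) | (p_new > hi) | ~np.isfinite(p_new)
        p = np.where(bad, 0.5 * (lo + hi), p_new)
    else:
        raise InvalidStateError("capillary dissociation-curve inversion did not converge")
    return p, chem.o2_content(p)


def capillary_step(
    train: CapillaryTrain,
    inlet_content: float,
    p_alv_mmhg: float,
    dl_effective_ml_mmhg_min: float,
    dt_s: float,
) -> CapillaryTrain:
    """Advance a capillary train by one implicit serial sweep, inlet to outlet.

    Each division obeys

        dC_i/dt = k_flow * (C_{i-1} - C_i) + k_diff*D_L * (P_Alv - P_c,i)

    with P_c,i recovered from C_i through the dissociation curve.  The sweep
    is sequential because division i's inlet is division i-1's new value.
    The train is updated in place and returned.
    """
    if inlet_content < 0:
        raise InvalidStateError("negative capillary inlet content")
    k_flow, k_diff_per_dl = capillary_rate_coefficients(
        train.n, train.q_c_ml_min, train.v_capillary_ml, train.f_k
    )
    a_flow = dt_s * k_flow
    a_diff = dt_s * k_diff_per_dl * dl_effective_ml_mmhg_min
    c_in = float(inlet_content)
    for i in range(train.n):
        try:
            p_new, c_new = _implicit_division_update(
                train.chemistry, train.gas,
                train.contents[i], c_in, train.pressures[i],
                p_alv_mmhg, a_flow, a_diff,
            )
        except InvalidStateError as exc:
            raise InvalidStateError(f"capillary division {i}: {exc}") from exc
        train.contents[i] = c_new
        train.pressures[i] = p_new
        c_in = float(c_new)
    return train


# -- mixing -----------------------------------------------------------------


def mix_arterial(end_capillary_contents, flow_fractions, venous_content, shunt):
    """Flow-weighted arterial recombination with a venous-admixture shunt.

    arterial = (1 - shunt) * sum_k f_Q,k * C_k / sum_k f_Q,k + shunt * C_ven
    """
    if not (0.0 <= shunt <= 1.0):
        raise DomainError(f"shunt must be in [0, 1], got {shunt}")
    c = np.asarray(end_capillary_contents, dtype=float)
    w = np.asarray(flow_fractions, dtype=float)
    if c.shape != w.shape:
        raise InvalidStateError(f"flow-weight mismatch: {c.shape} vs {w.shape}")
    if w.sum() <= 0 or np.any(w < 0):
        raise InvalidStateError("flow-weight mismatch: weights must be positive")
    mean_end = (c * w).sum(axis=-1) / w.sum()
    out = (1.0 - shunt) * mean_end + shunt * np.asarray(venous_content, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


# -- convenience re-exports (default chemistry) -----------------------------


def o2_saturation(p_o2, chemistry: BloodChemistry = DEFAULT_CHEMISTRY):
    """Hill-curve hemoglobin O2 saturation at ``p_o2`` mmHg."""
    return chemistry.o2_saturation(p_o2)


def o2_content(p_o2, chemistry: BloodChemistry = DEFAULT_CHEMISTRY):
    """Total blood O2 content (bound + dissolved), ml O2 / ml blood."""
    return chemistry.o2_content(p_o2)


def content_to_pressure(content, chemistry: BloodChemistry = DEFAULT_CHEMISTRY):
    """Invert the O2 content curve back to partial pressure."""
    return chemistry.o2_pressure_from_content(content)
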