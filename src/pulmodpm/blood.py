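"""Blood gas chemistry: O2 via a Hill dissociation curve, CO2 linearized.

O2 content combines hemoglobin-bound and dissolved fractions,

    S(P)  = P^n / (P^n + P50^n)
    C(P)  = capacity * Hb * S(P) + beta_O2 * P      [ml O2 / ml blood]

with defaults P50 = 26.8 mmHg, n = 2.7, capacity 1.34 ml/g, Hb 15 g/dl,
beta_O2 = 3e-5 ml/(ml mmHg).  CO2 content uses a linearized Douglas-type
curve C = a + b*P, adequate near the physiologic operating point.  Both
curves are strictly increasing, hence invertible; inversion is by damped
Newton in pressure with a bisection fallback.

A ``linear_o2_beta`` override replaces the O2 curve by C = beta*P, which has
closed-form exchange solutions and is used by the analytic test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["BloodChemistry", "DEFAULT_CHEMISTRY"]

_P_MAX = 1500.0  # mmHg; upper bracket for inversions


@dataclass(frozen=True)
class BloodChemistry:
    hb_g_dl: float = 15.0
    p50_mmhg: float = 26.8
    hill_n: float = 2.7
    o2_capacity_ml_g: float = 1.34
    beta_o2: float = 3.0e-5  # dissolved O2, ml/(ml blood * mmHg)
    co2_slope: float = 0.0057  # ml/(ml blood * mmHg)
    co2_intercept: float = 0.252  # ml/ml at P = 0 (linearization offset)
    linear_o2_beta: float | None = None  # test/oracle mode: C = beta * P

    @property
    def o2_capacity_ml_ml(self) -> float:
        """Hb-bound O2 capacity per ml blood."""
        return self.o2_capacity_ml_g * self.hb_g_dl / 100.0

    # -- O2 ------------------------------------------------------------------

    def o2_saturation(self, p_o2):
        p = np.asarray(p_o2, dtype=float)
        if np.any(p < 0):
            raise DomainError("P_O2 must be non-negative")
        with np.errstate(divide="ignore"):
            r = (p / self.p50_mmhg) ** self.hill_n
        s = r / (1.0 + r)
        return float(s) if s.ndim == 0 else s

    def o2_content(self, p_o2):
        if self.linear_o2_beta is not None:
            p = np.asarray(p_o2, dtype=float)
            out = self.linear_o2_beta * p
            return float(out) if out.ndim == 0 else out
        s = self.o2_saturation(p_o2)
        return self.o2_capacity_ml_ml * s + self.beta_o2 * np.asarray(p_o2, dtype=float)

    def o2_content_derivative(self, p_o2):
        """dC/dP of the O2 curve, used by the implicit exchange solver."""
        if self.linear_o2_beta is not None:
            return np.full_like(np.asarray(p_o2, dtype=float), self.linear_o2_beta)
        p = np.asarray(p_o2, dtype=float)
        n, p50 = self.hill_n, self.p50_mmhg
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (p / p50) ** n
            ds = np.where(p > 0, n * r / (p * (1.0 + r) ** 2), 0.0)
        return self.o2_capacity_ml_ml * ds + self.beta_o2

    def o2_pressure_from_content(self, content):
        """Invert the O2 content curve (bijective on [0, P_max])."""
        if self.linear_o2_beta is not None:
            out = np.asarray(content, dtype=float) / self.linear_o2_beta
            return float(out) if out.ndim == 0 else out
        c = np.atleast_1d(np.asarray(content, dtype=float))
        if np.any(c < 0) or np.any(c > self.o2_content(_P_MAX) + 1e-12):
            raise DomainError("O2 content outside the physical range")
        # Hill-only initial guess, then damped Newton with bisection safeguard
        s0 = np.clip(c / self.o2_capacity_ml_ml, 1e-9, 1.0 - 1e-6)
        p = self.p50_mmhg * (s0 / (1.0 - s0)) ** (1.0 / self.hill_n)
        lo = np.zeros_like(c)
        hi = np.full_like(c, _P_MAX)
        for _ in range(60):
            f = self.o2_content(p) - c
            hi = np.where(f > 0, p, hi)
            lo = np.where(f < 0, p, lo)
            step = f / self.o2_content_derivative(p)
            p_new = p - step
            bad = (p_new <= lo) | (p_new >= hi) | ~np.isfinite(p_new)
            p = np.where(bad, 0.5 * (lo + hi), p_new)
            if np.all(np.abs(step) < 1e-10):
                break
        return float(p[0]) if np.isscalar(content) or np.ndim(content) == 0 else p

    # -- CO2 -----------------------------------------------------------------

    def co2_content(self, p_co2):
        p = np.asarray(p_co2, dtype=float)
        out = self.co2_intercept + self.co2_slope * p
        return float(out) if out.ndim == 0 else out

    def co2_pressure_from_content(self, content):
        c = np.asarray(content, dtype=float)
        out = np.maximum(0.0, (c - self.co2_intercept) / self.co2_slope)
        return float(out) if out.ndim == 0 else out

    def linear_coeffs(self, gas: str) -> tuple[float, float] | None:
        """(a, b) with C = a + b*P when the curve for ``gas`` is affine, else None.

        Lets implicit exchange solvers take a closed-form path instead of
        Newton iteration (CO2 always; O2 only in linear oracle mode).
        """
        if gas == "CO2":
            return (self.co2_intercept, self.co2_slope)
        if self.linear_o2_beta is not None:
            return (0.0, self.linear_o2_beta)
        return None

    # -- dispatch ------------------------------------------------------------

    def content(self, gas: str, p):
        return self.o2_content(p) if gas == "O2" else self.co2_content(p)

    def pressure_from_content(self, gas: str, c):
        if gas == "O2":
            return self.o2_pressure_from_content(c)
        return self.co2_pressure_from_content(c)

    def content_derivative(self, gas: str, p):
        if gas == "O2":
            return self.o2_content_derivative(p)
        return np.full_like(np.asarray(p, dtype=float), self.co2_slope)


DEFAULT_CHEMISTRY = BloodChemistry()
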