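"""Gravity-dependent regional ventilation and perfusion.

Regional ventilation and capillary perfusion both decrease linearly with
height above the lung base (the classic upright-posture gradient), with
perfusion falling roughly three times faster than ventilation.  The linear
weights below give flow per percent of lung volume as a function of segment
height h (% from base):

    ventilation weight:  -0.00031 * h + 0.064
    perfusion weight:    -0.0009  * h + 0.1

A segment's flow fraction is its weight times its volume fraction,
renormalized over all segments so each flow vector partitions unity.  The
weights are regressions of normalized regional rates, not a partition of
unity themselves, hence the renormalization.  Fractions are static per
anatomy: damage acts through diffusing capacity and shunt, not through
redistribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import LungSegment
from .errors import DomainError, InvalidStateError

__all__ = [
    "VENTILATION_SLOPE",
    "VENTILATION_INTERCEPT",
    "PERFUSION_SLOPE",
    "PERFUSION_INTERCEPT",
    "ventilation_weight",
    "perfusion_weight",
    "segment_flow_fractions",
    "FlowFractions",
]

VENTILATION_SLOPE = -0.00031
VENTILATION_INTERCEPT = 0.064
PERFUSION_SLOPE = -0.0009
PERFUSION_INTERCEPT = 0.1


def _linear_weight(h, slope: float, intercept: float):
    h = np.asarray(h, dtype=float)
    if np.any(h < 0.0) or np.any(h > 100.0):
        raise DomainError(f"height must be in [0, 100] % from base, got {h}")
    out = slope * h + intercept
    return float(out) if out.ndim == 0 else out


def ventilation_weight(h):
    """Ventilation per percent lung volume at height ``h`` (% from base)."""
    return _linear_weight(h, VENTILATION_SLOPE, VENTILATION_INTERCEPT)


def perfusion_weight(h):
    """Capillary perfusion per percent lung volume at height ``h`` (% from base)."""
    return _linear_weight(h, PERFUSION_SLOPE, PERFUSION_INTERCEPT)


@dataclass(frozen=True)
class FlowFractions:
    """Normalized per-segment flow partitions (each sums to 1)."""

    segment_ids: tuple[int, ...]
    ventilation: np.ndarray  # f_V,k
    perfusion: np.ndarray  # f_Q,k

    def __post_init__(self) -> None:
        for name in ("ventilation", "perfusion"):
            v = getattr(self, name)
            if abs(float(v.sum()) - 1.0) > 1e-9 or np.any(v <= 0) or np.any(v > 1):
                raise InvalidStateError(f"{name} fractions must lie in (0,1] and sum to 1")


def segment_flow_fractions(
    segments: list[LungSegment], kind: str | None = None
) -> FlowFractions | np.ndarray:
    """Fractional flows for each segment from its height and volume fraction.

    fraction_k = weight(h_k) * vol_k / sum_j weight(h_j) * vol_j

    With ``kind`` in {"ventilation", "perfusion"} returns the single
    normalized vector; with ``kind=None`` returns both as a FlowFractions.
    """
    if not segments:
        raise InvalidStateError("empty segment list")
    h = np.array([s.height_pct for s in segments], dtype=float)
    vol = np.array([s.volume_fraction for s in segments], dtype=float)

    def _norm(weights: np.ndarray) -> np.ndarray:
        raw = weights * vol
        return raw / raw.sum()

    fv = _norm(ventilation_weight(h))
    fq = _norm(perfusion_weight(h))
    if kind == "ventilation":
        return fv
    if kind == "perfusion":
        return fq
    if kind is not None:
        raise DomainError(f"unknown flow kind {kind!r}")
    return FlowFractions(
        segment_ids=tuple(s.id for s in segments), ventilation=fv, perfusion=fq
    )
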