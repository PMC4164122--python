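"""Toy lungs and synthetic calibration data for testing and oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .anatomy import AirwayCompartment, LungModel, LungSegment
from .errors import InvalidParameterError

__all__ = ["make_fixture_lung", "generate_calibration_data"]


def make_fixture_lung(
    n_segments: int = 1,
    symmetric: bool = True,
    heights=None,
    body_mass_kg: float = 70.0,
    upper_volume_ml: float = 10.0,
    deadspace_per_segment_ml: float = 2.0,
    v_alveolar_total_ml: float = 3000.0,
    v_capillary_total_ml: float = 75.0,
) -> LungModel:
    """Miniature lung: one tracheal compartment feeding ``n_segments`` equal
    segments, with analytic-friendly (small) conducting volumes.

    ``symmetric`` places all segments at mid-height 50%; otherwise pass
    explicit ``heights`` (% from base).  Useful for comparing the engine to
    closed-form two-compartment solutions and for symmetry tests.
    """
    if n_segments < 1:
        raise InvalidParameterError("need at least one segment")
    if heights is None:
        heights = [50.0] * n_segments if symmetric else list(
            np.linspace(0.0, 100.0, n_segments)
        )
    if len(heights) != n_segments:
        raise InvalidParameterError("heights length must match n_segments")

    # single airway 'trachea'; diameter back-computed from the volume
    length = 100.0
    diameter = float(np.sqrt(4.0 * upper_volume_ml * 1000.0 / (np.pi * length)))
    trachea = AirwayCompartment(id=1, length_mm=length, diameter_mm=diameter,
                                volume_ml=upper_volume_ml)
    segments = [
        LungSegment(
            id=19 + k,
            volume_fraction=1.0 / n_segments,
            height_pct=float(heights[k]),
            conducting_deadspace_volume_ml=deadspace_per_segment_ml,
            feeding_airway_id=1,
            side="left" if k < n_segments // 2 else "right",
        )
        for k in range(n_segments)
    ]
    model = LungModel(
        species="human",
        body_mass_kg=body_mass_kg,
        reference_mass_kg=body_mass_kg,
        airway_compartments=[trachea],
        segments=segments,
        v_capillary_total_ml=v_capillary_total_ml,
        v_alveolar_total_ml=v_alveolar_total_ml,
    )
    model.validate()
    return model


def generate_calibration_data(
    slope: float = 0.15,
    intercept: float = 0.0,
    noise_sigma: float = 0.01,
    n: int = 20,
    seed: int = 0,
    x_max: float = 1.0,
    x_kind: str = "dl_reduction",
    path=None,
) -> pd.DataFrame:
    """Reproducible synthetic shunt-vs-damage calibration points.

    Draws ``n`` x values uniformly on [0, x_max] and shunt = intercept +
    slope*x + N(0, sigma), clipped at 0.  Stands in for figure-read
    calibration sets.  Written as CSV when ``path`` is given.
    """
    if n < 2 or noise_sigma < 0:
        raise InvalidParameterError("need n >= 2 and sigma >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, x_max, size=n)
    y = np.clip(intercept + slope * x + rng.normal(0.0, noise_sigma, size=n), 0.0, None)
    df = pd.DataFrame({
        "condition": [f"synthetic_{i}" for i in range(n)],
        "x_kind": x_kind,
        "x_value": x,
        "shunt": y,
    })
    if path is not None:
        df.to_csv(path, index=False)
    return df
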