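"""Species-specific lung structures built from morphometric tables.

The human model is an 18-compartment asymmetric upper airway tree (trachea to
segmental bronchi, Horsfield-style morphometry) feeding 19 lung segments, each
of which carries a conducting dead-space compartment in series with a
variable-volume alveolar compartment and a capillary train.  The sheep model
is a 6-compartment tree feeding 6 lobar alveolar compartments; the goat uses
sheep anatomy scaled by body mass.

Airway/segment dimensions are shipped as TSV resources mirroring the source
morphometric tables; tree connectivity and the left/right segment partition
are shipped as separate adopted maps (the morphometric tables do not print
them).  Lengths and diameters are millimetres throughout.

Allometric scaling: volumes scale linearly with body mass, area-like
quantities (diffusing capacities) with mass to the 2/3 power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources as _ilres

import pandas as pd

from .errors import InvalidParameterError, InvalidStateError

__all__ = [
    "AirwayCompartment",
    "LungSegment",
    "LungModel",
    "REFERENCE_MASS_KG",
    "build_human_lung",
    "build_sheep_lung",
    "build_goat_lung",
    "scale_anatomy",
    "load_resource_table",
]

#: Reference body masses (kg) at which the shipped tables apply.
REFERENCE_MASS_KG = {"human": 70.0, "sheep": 40.0, "goat": 30.0}

#: Unscaled human reference diffusing capacities, ml/(mmHg*min).
DL_O2_REFERENCE = 40.0
DL_CO2_REFERENCE = 800.0

#: Default total pulmonary capillary volume at human reference mass, ml.
V_CAPILLARY_REFERENCE_ML = 75.0

#: Default end-expiratory (functional residual) alveolar volume, human, ml.
V_ALVEOLAR_REFERENCE_ML = 3000.0

#: Default total anatomic dead space target at human reference mass, ml.
DEADSPACE_REFERENCE_ML = 150.0

#: Baseline (healthy) shunt fraction of cardiac output.
SHUNT_BASELINE = 0.02


def load_resource_table(name: str) -> pd.DataFrame:
    """Load one of the shipped TSV resource tables by file name."""
    ref = _ilres.files("pulmodpm").joinpath("resources").joinpath(name)
    with _ilres.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


@dataclass
class AirwayCompartment:
    """A rigid, well-mixed conducting airway compartment.

    ``volume_ml`` is the cylinder volume pi*d^2*l/4 unless the source table
    gives a measured volume directly (sheep).
    """

    id: int
    length_mm: float
    diameter_mm: float
    volume_ml: float
    parent_id: int | None = None
    child_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.volume_ml <= 0 or self.length_mm <= 0 or self.diameter_mm <= 0:
            raise InvalidStateError(
                f"airway compartment {self.id}: non-positive dimension"
            )


def _cylinder_volume_ml(length_mm: float, diameter_mm: float) -> float:
    return math.pi * diameter_mm**2 * length_mm / 4.0 / 1000.0


@dataclass
class LungSegment:
    """A lung segment (or lobe): dead space + alveolar unit + capillary bed.

    ``volume_fraction`` is the fraction of total alveolar volume (the f_k of
    the exchange equations, also used as the membrane-area fraction);
    ``height_pct`` is the mean segment height as % of lung height from the
    base, which drives the gravitational ventilation/perfusion gradients.
    """

    id: int
    volume_fraction: float
    height_pct: float
    conducting_deadspace_volume_ml: float
    feeding_airway_id: int
    side: str = ""  # "left" | "right"

    def __post_init__(self) -> None:
        if not (0.0 <= self.height_pct <= 100.0):
            raise InvalidStateError(f"segment {self.id}: height {self.height_pct} outside [0, 100]")
        if self.volume_fraction <= 0:
            raise InvalidStateError(f"segment {self.id}: non-positive volume fraction")


@dataclass
class LungModel:
    """Full anatomic lung structure for one species at one body mass."""

    species: str
    body_mass_kg: float
    reference_mass_kg: float
    airway_compartments: list[AirwayCompartment]
    segments: list[LungSegment]
    dl_o2_ref: float = DL_O2_REFERENCE
    dl_co2: float = DL_CO2_REFERENCE
    v_capillary_total_ml: float = V_CAPILLARY_REFERENCE_ML
    v_alveolar_total_ml: float = V_ALVEOLAR_REFERENCE_ML
    shunt_baseline: float = SHUNT_BASELINE

    # -- structure queries ---------------------------------------------------

    def airway(self, airway_id: int) -> AirwayCompartment:
        return self._airway_index()[airway_id]

    def _airway_index(self) -> dict[int, AirwayCompartment]:
        if not hasattr(self, "_aw_idx") or len(self._aw_idx) != len(self.airway_compartments):
            self._aw_idx = {c.id: c for c in self.airway_compartments}
        return self._aw_idx

    def segment(self, segment_id: int) -> LungSegment:
        for s in self.segments:
            if s.id == segment_id:
                return s
        raise KeyError(segment_id)

    @property
    def root_id(self) -> int:
        roots = [c.id for c in self.airway_compartments if c.parent_id is None]
        if len(roots) != 1:
            raise InvalidStateError(f"expected exactly one root airway, found {roots}")
        return roots[0]

    def path_to_root(self, airway_id: int) -> list[int]:
        """Airway ids from ``airway_id`` up to (and including) the trachea."""
        idx = self._airway_index()
        path, cur = [airway_id], idx[airway_id]
        seen = {airway_id}
        while cur.parent_id is not None:
            pid = cur.parent_id
            if pid in seen:
                raise InvalidStateError("airway tree contains a cycle")
            path.append(pid)
            seen.add(pid)
            cur = idx[pid]
        return path

    def subtended_segments(self, airway_id: int) -> list[int]:
        """Segments whose feeding path passes through ``airway_id``."""
        out = []
        for s in self.segments:
            if airway_id in self.path_to_root(s.feeding_airway_id):
                out.append(s.id)
        return out

    def segments_on_side(self, side: str) -> list[int]:
        return [s.id for s in self.segments if s.side == side]

    @property
    def anatomic_deadspace_ml(self) -> float:
        """Total conducting volume: upper tree plus per-segment dead space."""
        return sum(c.volume_ml for c in self.airway_compartments) + sum(
            s.conducting_deadspace_volume_ml for s in self.segments
        )

    def validate(self) -> None:
        """Check the structural invariants; raise InvalidStateError on failure."""
        _ = self.root_id
        idx = self._airway_index()
        for c in self.airway_compartments:
            if c.parent_id is not None and c.parent_id not in idx:
                raise InvalidStateError(f"airway {c.id}: orphan (parent {c.parent_id} missing)")
            _ = self.path_to_root(c.id)  # raises on cycles
        fsum = sum(s.volume_fraction for s in self.segments)
        if abs(fsum - 1.0) > 1e-9:
            raise InvalidStateError(f"segment volume fractions sum to {fsum}, not 1")
        # every upper-tree terminal must feed at least one segment, and every
        # segment's conducting compartment (the true leaf) exactly one segment
        fed_by = {s.feeding_airway_id for s in self.segments}
        for c in self.airway_compartments:
            if not c.child_ids and c.id not in fed_by:
                raise InvalidStateError(f"terminal airway {c.id} feeds no segment")


# -- builders ---------------------------------------------------------------


def _check_mass(body_mass_kg: float) -> None:
    if not (body_mass_kg > 0) or not math.isfinite(body_mass_kg):
        raise InvalidParameterError(f"body mass must be positive, got {body_mass_kg}")


def build_human_lung(
    body_mass_kg: float = 70.0,
    deadspace_total_ml: float = DEADSPACE_REFERENCE_ML,
) -> LungModel:
    """Construct the 19-segment human lung at ``body_mass_kg``.

    The shipped tables describe a 70 kg reference subject; other masses are
    produced by allometric scaling.  ``deadspace_total_ml`` is the target
    total anatomic dead space at reference mass; the part not accounted for
    by the upper tree is distributed over the per-segment conducting
    compartments in proportion to segment volume fraction.
    """
    _check_mass(body_mass_kg)
    airways_tbl = load_resource_table("human_airways.tsv")
    tree_tbl = load_resource_table("human_airway_tree.tsv")
    seg_tbl = load_resource_table("human_segments.tsv")
    map_tbl = load_resource_table("human_segment_map.tsv")

    compartments = {
        int(r.id): AirwayCompartment(
            id=int(r.id),
            length_mm=float(r.length_mm),
            diameter_mm=float(r.diameter_mm),
            volume_ml=_cylinder_volume_ml(float(r.length_mm), float(r.diameter_mm)),
        )
        for r in airways_tbl.itertuples()
    }
    for r in tree_tbl.itertuples():
        compartments[int(r.child_id)].parent_id = int(r.parent_id)
        compartments[int(r.parent_id)].child_ids.append(int(r.child_id))

    upper_volume = sum(c.volume_ml for c in compartments.values())
    conducting_total = max(0.0, deadspace_total_ml - upper_volume)

    vol_pct = dict(zip(seg_tbl["id"].astype(int), seg_tbl["volume_pct"].astype(float)))
    height = dict(zip(seg_tbl["id"].astype(int), seg_tbl["height_pct"].astype(float)))
    feeding = dict(zip(map_tbl["segment_id"].astype(int), map_tbl["feeding_airway_id"].astype(int)))
    side = dict(zip(map_tbl["segment_id"].astype(int), map_tbl["side"]))
    total_pct = sum(vol_pct.values())

    segments = [
        LungSegment(
            id=sid,
            volume_fraction=vol_pct[sid] / total_pct,
            height_pct=height[sid],
            conducting_deadspace_volume_ml=conducting_total * vol_pct[sid] / total_pct,
            feeding_airway_id=feeding[sid],
            side=str(side[sid]),
        )
        for sid in sorted(vol_pct)
    ]

    model = LungModel(
        species="human",
        body_mass_kg=REFERENCE_MASS_KG["human"],
        reference_mass_kg=REFERENCE_MASS_KG["human"],
        airway_compartments=sorted(compartments.values(), key=lambda c: c.id),
        segments=segments,
    )
    model.validate()
    if body_mass_kg != model.reference_mass_kg:
        model = scale_anatomy(model, body_mass_kg)
    return model


def _build_ovine(species: str, body_mass_kg: float) -> LungModel:
    _check_mass(body_mass_kg)
    dims = load_resource_table("sheep_dimensions.tsv")
    tree_tbl = load_resource_table("sheep_airway_tree.tsv")
    lobe_tbl = load_resource_table("sheep_lobe_map.tsv")

    airway_rows = dims[~dims["volume"].astype(str).str.endswith("%")]
    lobe_rows = dims[dims["volume"].astype(str).str.endswith("%")]

    compartments = {}
    for r in airway_rows.itertuples():
        vol = float(r.volume)
        length = float(r.length_mm)
        diameter = math.sqrt(4.0 * vol * 1000.0 / (math.pi * length))  # back out from volume
        compartments[int(r.id)] = AirwayCompartment(
            id=int(r.id), length_mm=length, diameter_mm=diameter, volume_ml=vol
        )
    for r in tree_tbl.itertuples():
        compartments[int(r.child_id)].parent_id = int(r.parent_id)
        compartments[int(r.parent_id)].child_ids.append(int(r.child_id))

    ref_mass = REFERENCE_MASS_KG["sheep"]
    mass_lin = ref_mass / REFERENCE_MASS_KG["human"]
    deadspace_total = DEADSPACE_REFERENCE_ML * mass_lin
    upper_volume = sum(c.volume_ml for c in compartments.values())
    conducting_total = max(0.0, deadspace_total - upper_volume)

    vol_pct = {int(r.id): float(str(r.volume).rstrip("%")) for r in lobe_rows.itertuples()}
    total_pct = sum(vol_pct.values())  # 100.1 in the source table; renormalized
    feeding = dict(zip(lobe_tbl["lobe_id"].astype(int), lobe_tbl["feeding_airway_id"].astype(int)))
    side = dict(zip(lobe_tbl["lobe_id"].astype(int), lobe_tbl["side"]))
    height = dict(zip(lobe_tbl["lobe_id"].astype(int), lobe_tbl["height_pct"].astype(float)))

    segments = [
        LungSegment(
            id=sid,
            volume_fraction=vol_pct[sid] / total_pct,
            height_pct=height[sid],
            conducting_deadspace_volume_ml=conducting_total * vol_pct[sid] / total_pct,
            feeding_airway_id=feeding[sid],
            side=str(side[sid]),
        )
        for sid in sorted(vol_pct)
    ]

    model = LungModel(
        species=species,
        body_mass_kg=ref_mass,
        reference_mass_kg=ref_mass,
        airway_compartments=sorted(compartments.values(), key=lambda c: c.id),
        segments=segments,
        dl_o2_ref=DL_O2_REFERENCE * mass_lin ** (2.0 / 3.0),
        dl_co2=DL_CO2_REFERENCE * mass_lin ** (2.0 / 3.0),
        v_capillary_total_ml=V_CAPILLARY_REFERENCE_ML * mass_lin,
        v_alveolar_total_ml=V_ALVEOLAR_REFERENCE_ML * mass_lin,
    )
    model.validate()
    if body_mass_kg != ref_mass:
        model = scale_anatomy(model, body_mass_kg)
    return model


def build_sheep_lung(body_mass_kg: float = 40.0) -> LungModel:
    """Construct the 6-lobe sheep lung (lobar alveolar compartments, ids 19-24)."""
    return _build_ovine("sheep", body_mass_kg)


def build_goat_lung(body_mass_kg: float = 30.0) -> LungModel:
    """Goat lung: sheep structure, scaled to goat body mass."""
    _check_mass(body_mass_kg)
    model = _build_ovine("goat", REFERENCE_MASS_KG["sheep"])
    model = scale_anatomy(model, body_mass_kg)
    return model


def scale_anatomy(model: LungModel, target_mass_kg: float) -> LungModel:
    """Allometrically scale a lung model by ``target_mass_kg / reference_mass``.

    Volumes scale linearly with the mass ratio; diffusing capacities (membrane
    area terms) with the mass ratio to the 2/3 power.  Dimensionless fractions
    and heights are unchanged.  The scale factor is always taken against the
    model's reference mass, so repeated scaling compounds.
    """
    _check_mass(target_mass_kg)
    ratio = target_mass_kg / model.reference_mass_kg
    lin = ratio
    area = ratio ** (2.0 / 3.0)
    length = ratio ** (1.0 / 3.0)

    airways = [
        replace(
            c,
            length_mm=c.length_mm * length,
            diameter_mm=c.diameter_mm * length,
            volume_ml=c.volume_ml * lin,
            child_ids=list(c.child_ids),
        )
        for c in model.airway_compartments
    ]
    segments = [
        replace(s, conducting_deadspace_volume_ml=s.conducting_deadspace_volume_ml * lin)
        for s in model.segments
    ]
    return LungModel(
        species=model.species,
        body_mass_kg=target_mass_kg,
        reference_mass_kg=model.reference_mass_kg,
        airway_compartments=airways,
        segments=segments,
        dl_o2_ref=model.dl_o2_ref * area,
        dl_co2=model.dl_co2 * area,
        v_capillary_total_ml=model.v_capillary_total_ml * lin,
        v_alveolar_total_ml=model.v_alveolar_total_ml * lin,
        shunt_baseline=model.shunt_baseline,
    )
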