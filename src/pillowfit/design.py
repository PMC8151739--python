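"""From per-partition support requirements to a pore-array material design.

Each partition must compress from the uncompressed foam height to the
height prescribed by the group's ergonomic contour node while carrying that
partition's share of the head/neck load.  The required equivalent stiffness
is ``k_i = dF_i / dH_i`` (N/mm), with the partition force integrated from
the ideal pressure matrix (1 kPa x 1 cm^2 = 0.1 N).

Local stiffness is realized by drilling a staggered array of holes in the
foam: larger pores soften the material.  The measured calibration (pore
diameter d vs. equivalent elastic coefficient k) follows a power law
``d = a k^b`` fitted by log-log least squares; predicted diameters are
clamped into the calibration's valid range rather than extrapolated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import PressureMatrix
from .ideal import IdealMatrix
from .segmentation import PartitionMap
from . import reference

__all__ = [
    "ElasticCalibration",
    "PartitionGeometry",
    "GeometryEntry",
    "ContourNodes",
    "PoreLayout",
    "Hole",
    "required_stiffness",
    "partition_force",
    "fit_power_law",
    "pore_diameter",
    "compressed_geometry",
    "pore_layout",
]


def fit_power_law(pairs: Sequence[Tuple[float, float]]) -> Tuple[float, float, float]:
    """Fit ``d = a k^b`` by ordinary least squares in log-log space.

    Returns ``(a, b, r_squared)``. Requires at least three strictly
    positive (d, k) pairs.
    """
    if len(pairs) < 3:
        raise ValueError("need at least three (d, k) pairs to fit")
    d = np.array([p[0] for p in pairs], dtype=float)
    k = np.array([p[1] for p in pairs], dtype=float)
    if np.any(d <= 0) or np.any(k <= 0):
        raise ValueError("all diameters and stiffness values must be positive")
    ld, lk = np.log(d), np.log(k)
    b, lna = np.polyfit(lk, ld, 1)
    pred = lna + b * lk
    ss_res = float(((ld - pred) ** 2).sum())
    ss_tot = float(((ld - ld.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(np.exp(lna)), float(b), r2


@dataclass(frozen=True)
class ElasticCalibration:
    """Pore-diameter vs. equivalent-stiffness calibration with fitted power law.

    ``pairs`` must be sorted by increasing diameter with strictly decreasing
    stiffness (bigger holes are softer).  Predictions outside
    ``valid_d_range_mm`` are clamped, not extrapolated.
    """

    pairs: Tuple[Tuple[float, float], ...]
    a: float
    b: float
    r_squared: float
    valid_d_range_mm: Tuple[float, float] = reference.VALID_D_RANGE_MM
    foam_height_mm: float = reference.FOAM_HEIGHT_MM
    pitch_mm: float = reference.HOLE_PITCH_MM

    def __post_init__(self) -> None:
        d = [p[0] for p in self.pairs]
        k = [p[1] for p in self.pairs]
        if any(d2 <= d1 for d1, d2 in zip(d, d[1:])):
            raise ValueError("calibration pairs must have strictly increasing diameters")
        if any(k2 >= k1 for k1, k2 in zip(k, k[1:])):
            raise ValueError("stiffness must strictly decrease as pore diameter grows")

    @classmethod
    def fit(
        cls,
        pairs: Sequence[Tuple[float, float]],
        valid_d_range_mm: Tuple[float, float] = reference.VALID_D_RANGE_MM,
        foam_height_mm: float = reference.FOAM_HEIGHT_MM,
        pitch_mm: float = reference.HOLE_PITCH_MM,
    ) -> "ElasticCalibration":
        a, b, r2 = fit_power_law(pairs)
        return cls(
            pairs=tuple((float(d), float(k)) for d, k in pairs),
            a=a,
            b=b,
            r_squared=r2,
            valid_d_range_mm=valid_d_range_mm,
            foam_height_mm=foam_height_mm,
            pitch_mm=pitch_mm,
        )

    @classmethod
    def from_reference(cls) -> "ElasticCalibration":
        """The packaged 110 mm / 60 D memory-foam calibration."""
        return cls.fit(reference.ELASTIC_CALIBRATION_PAIRS)


def required_stiffness(total_force_n: float, height_change_mm: float) -> float:
    """Equivalent stiffness requirement ``k = dF / dH`` in N/mm."""
    if height_change_mm <= 0:
        raise ValueError("height change must be positive")
    return float(total_force_n) / float(height_change_mm)


def partition_force(m: PressureMatrix, pm: PartitionMap) -> Dict[str, float]:
    """Total normal force per partition in N.

    ``dF = sum_cells P(kPa) * cell_area(cm^2) * 0.1`` (1 kPa cm^2 = 0.1 N).
    An empty partition contributes 0 N with a warning.
    """
    if pm.labels.shape != m.shape:
        raise ValueError("partition map and matrix grids differ")
    area = m.cell_area_cm2
    out: Dict[str, float] = {}
    for label, name in sorted(pm.names.items()):
        mask = pm.labels == label
        if not mask.any():
            warnings.warn(f"partition {name!r} is empty; force set to 0 N", stacklevel=2)
            out[name] = 0.0
            continue
        out[name] = float(m.values[mask].sum() * area * 0.1)
    return out


def pore_diameter(k: float, calibration: ElasticCalibration) -> Tuple[float, bool]:
    """Pore diameter for a target stiffness: ``d = a k^b``, clamped.

    Returns ``(d_mm, clamped)`` where ``clamped`` flags that the raw
    prediction fell outside the calibration's valid diameter range.
    """
    if k <= 0:
        raise ValueError("stiffness must be positive")
    raw = calibration.a * k ** calibration.b
    lo, hi = calibration.valid_d_range_mm
    d = min(max(raw, lo), hi)
    return float(d), bool(d != raw)


@dataclass(frozen=True)
class ContourNodes:
    """Key ergonomic node per partition for one anthropometric group.

    ``nodes`` maps partition name -> (node name, x position mm, compression
    depth mm).  The depth is how far the node sinks below the uncompressed
    foam surface, so it equals the height change dH of that partition.
    """

    group: str
    nodes: Dict[str, Tuple[str, float, float]]
    foam_height_mm: float = reference.FOAM_HEIGHT_MM

    def __post_init__(self) -> None:
        for part, (name, x, depth) in self.nodes.items():
            if not (0 <= depth <= self.foam_height_mm):
                raise ValueError(
                    f"node depth {depth} mm for {part} outside [0, {self.foam_height_mm}]"
                )

    def depth(self, partition: str) -> float:
        return self.nodes[partition][2]


@dataclass(frozen=True)
class GeometryEntry:
    total_force_n: float
    height_change_mm: float
    compressed_height_mm: float
    required_k: float


@dataclass(frozen=True)
class PartitionGeometry:
    """Per-partition compressed geometry and stiffness requirement."""

    group: str
    entries: Dict[str, GeometryEntry]
    foam_height_mm: float = reference.FOAM_HEIGHT_MM


def compressed_geometry(
    nodes: ContourNodes,
    ideal: IdealMatrix,
    pm: PartitionMap,
    foam_height_mm: Optional[float] = None,
) -> PartitionGeometry:
    """Combine contour-node depths with ideal partition forces.

    Per partition: ``dH`` = node depth, compressed height = foam height -
    depth, ``dF`` from :func:`partition_force` on the ideal matrix, and
    ``required_k = dF / dH``.  A zero node depth means no compression and
    is an error (the stiffness requirement would be unbounded).
    """
    h = foam_height_mm if foam_height_mm is not None else nodes.foam_height_mm
    forces = partition_force(ideal.matrix, pm)
    missing = set(forces) - set(nodes.nodes)
    if missing:
        raise ValueError(f"contour nodes missing for partitions: {sorted(missing)}")
    entries: Dict[str, GeometryEntry] = {}
    for name, force in forces.items():
        depth = nodes.depth(name)
        if depth <= 0:
            raise ValueError(f"partition {name!r} has zero node depth (no compression)")
        if depth >= h:
            raise ValueError(f"partition {name!r} node depth {depth} mm >= foam height {h} mm")
        entries[name] = GeometryEntry(
            total_force_n=force,
            height_change_mm=depth,
            compressed_height_mm=h - depth,
            required_k=required_stiffness(force, depth),
        )
    return PartitionGeometry(group=nodes.group, entries=entries, foam_height_mm=h)


@dataclass(frozen=True)
class Hole:
    x_mm: float
    y_mm: float
    diameter_mm: float
    partition: str
    clamped: bool


@dataclass(frozen=True)
class PoreLayout:
    """Staggered (hex-offset) hole array realizing per-partition stiffness."""

    holes: Tuple[Hole, ...]
    pitch_mm: float
    bounds_mm: Tuple[float, float]  # (width, height) of the footprint

    @property
    def diameters(self) -> Dict[str, float]:
        return {h.partition: h.diameter_mm for h in self.holes}


def staggered_lattice(
    width_mm: float, height_mm: float, pitch_mm: float
) -> List[Tuple[float, float]]:
    """Hex-offset lattice points inside [0, width] x [0, height].

    Rows are ``pitch * sqrt(3)/2`` apart; odd rows are shifted half a pitch.
    Nearest-neighbour distance is exactly ``pitch``.
    """
    pts: List[Tuple[float, float]] = []
    dy = pitch_mm * math.sqrt(3.0) / 2.0
    j = 0
    y = 0.0
    while y <= height_mm + 1e-9:
        x = (pitch_mm / 2.0) if (j % 2) else 0.0
        while x <= width_mm + 1e-9:
            pts.append((x, y))
            x += pitch_mm
        j += 1
        y = j * dy
    return pts


def pore_layout(
    geometry: PartitionGeometry,
    pm: PartitionMap,
    calibration: ElasticCalibration,
    pitch_cm: float = 1.1,
) -> PoreLayout:
    """Map per-partition pore diameters onto a staggered lattice.

    The sensor grid is mapped to millimetres via the sensor pitch; every
    lattice point falling on a labeled cell receives a hole with that
    partition's diameter; points on background get no hole.  Diameters at
    or above the hole pitch would overlap and are an error.
    """
    diam: Dict[str, Tuple[float, bool]] = {}
    for name, entry in geometry.entries.items():
        d, clamped = pore_diameter(entry.required_k, calibration)
        if d >= calibration.pitch_mm:
            raise ValueError(
                f"partition {name!r} needs pore diameter {d:.1f} mm >= "
                f"hole pitch {calibration.pitch_mm} mm (holes would overlap)"
            )
        diam[name] = (d, clamped)

    cell_mm = pitch_cm * 10.0
    rows, cols = pm.labels.shape
    width_mm, height_mm = cols * cell_mm, rows * cell_mm
    label_names = pm.names
    holes: List[Hole] = []
    for x, y in staggered_lattice(width_mm, height_mm, calibration.pitch_mm):
        r = min(rows - 1, int(y // cell_mm))
        c = min(cols - 1, int(x // cell_mm))
        label = int(pm.labels[r, c])
        if label == 0:
            continue
        name = label_names[label]
        if name not in diam:
            continue
        d, clamped = diam[name]
        holes.append(Hole(x, y, d, name, clamped))
    return PoreLayout(holes=tuple(holes), pitch_mm=calibration.pitch_mm, bounds_mm=(width_mm, height_mm))
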