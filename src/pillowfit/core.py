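"""Core data types and body-pressure-distribution indices.

A recording from a pressure-sensing mat is a 2D matrix of contact pressures
(kPa) on a regular sensor grid. Four scalar indices summarize how a support
surface loads the head and neck:

* ``Pv`` — average pressure (kPa), the central tendency of the load;
* ``Pm`` — peak pressure (kPa), the worst local load;
* ``Gm`` — maximum pressure gradient (kPa/cm^2), the sharpest spatial change;
* ``Gv`` — mean pressure gradient (kPa/cm^2), how concentrated the load is
  overall.

Two gradient conventions are provided.  The *literal* mode forms, for each
sensor row ``i >= 1``, the column-summed row difference
``G_i = sum_j (p[i, j] - p[i-1, j]) / l`` with ``l`` the sensor pitch; this
is a per-row quantity.  The *pointwise* mode computes a per-cell central
difference magnitude ``sqrt(gx^2 + gy^2)`` of the field sampled at pitch
``l``.  The unit label kPa/cm^2 is the one conventional in the pressure-mat
comfort literature and is carried for both modes.

Grid convention: row index 0 is the neck edge; rows increase toward the
parietal (crown) edge; cell (0, 0) is the top-left of the stored matrix.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np

__all__ = [
    "NoContactError",
    "Posture",
    "PressureMatrix",
    "ComfortScore",
    "TrialRecord",
    "PressureIndices",
    "average_pressure",
    "peak_pressure",
    "row_gradient_profile",
    "pointwise_gradient_field",
    "max_gradient",
    "mean_gradient",
    "pressure_indices",
    "partition_indices",
]


class NoContactError(ValueError):
    """Raised when an operation needs contact cells but none exist."""


class Posture(str, enum.Enum):
    SUPINE = "supine"
    LATERAL = "lateral"

    @classmethod
    def coerce(cls, value: "Posture | str") -> "Posture":
        return value if isinstance(value, Posture) else cls(str(value).lower())


@dataclass(frozen=True)
class PressureMatrix:
    """A 2D contact-pressure image (kPa) on a regular sensor grid.

    Parameters
    ----------
    values:
        ``(rows, cols)`` array of non-negative pressures in kPa.
    pitch_cm:
        Center-to-center sensor spacing in cm.
    contact_threshold_kpa:
        Pressures below this are treated as "no contact" wherever a
        contact-restricted statistic is requested.
    """

    values: np.ndarray
    pitch_cm: float = 1.1
    contact_threshold_kpa: float = 0.1

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"pressure matrix must be at least 2x2, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("pressure matrix contains non-finite values")
        if np.any(arr < 0):
            raise ValueError("pressure matrix contains negative pressures")
        if not self.pitch_cm > 0:
            raise ValueError("pitch_cm must be positive")
        if self.contact_threshold_kpa < 0:
            raise ValueError("contact_threshold_kpa must be >= 0")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def contact_mask(self) -> np.ndarray:
        return self.values >= self.contact_threshold_kpa

    @property
    def cell_area_cm2(self) -> float:
        return self.pitch_cm ** 2

    def with_values(self, values: np.ndarray) -> "PressureMatrix":
        return PressureMatrix(values, self.pitch_cm, self.contact_threshold_kpa)


@dataclass(frozen=True)
class ComfortScore:
    """Subjective comfort rating: four 1-5 items (higher = more comfortable)."""

    softness: int
    wrapping: int
    support: int
    fit: int

    def __post_init__(self) -> None:
        for name in ("softness", "wrapping", "support", "fit"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 5):
                raise ValueError(f"comfort sub-score {name}={v!r} must be an integer in 1..5")

    @property
    def subscores(self) -> tuple:
        return (self.softness, self.wrapping, self.support, self.fit)

    @property
    def total(self) -> int:
        return int(sum(self.subscores))


@dataclass(frozen=True)
class TrialRecord:
    """One (pillow, subject, posture) pressure recording with its rating.

    ``emg_valid`` flags that the subject's neck muscles were at electrical
    rest during the recording; only valid trials enter downstream analysis.
    """

    pillow_id: str
    subject_id: str
    posture: Posture
    matrix: PressureMatrix
    comfort: ComfortScore
    emg_valid: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "posture", Posture.coerce(self.posture))

    @property
    def trial_id(self) -> str:
        return f"{self.pillow_id}/{self.subject_id}"


@dataclass(frozen=True)
class PressureIndices:
    """The four pressure-distribution indices of one matrix or region."""

    Pv: float
    Pm: float
    Gm: float
    Gv: float

    def __post_init__(self) -> None:
        if not (0 <= self.Pv <= self.Pm + 1e-12):
            raise ValueError(f"require 0 <= Pv <= Pm, got Pv={self.Pv}, Pm={self.Pm}")
        if not (0 <= self.Gv <= self.Gm + 1e-12):
            raise ValueError(f"require 0 <= Gv <= Gm, got Gv={self.Gv}, Gm={self.Gm}")

    def delta(self, other: "PressureIndices") -> Dict[str, float]:
        """Element-wise self - other (measured minus ideal)."""
        return {
            "Pv": self.Pv - other.Pv,
            "Pm": self.Pm - other.Pm,
            "Gm": self.Gm - other.Gm,
            "Gv": self.Gv - other.Gv,
        }


# ---------------------------------------------------------------------------
# index operations
# ---------------------------------------------------------------------------


def average_pressure(m: PressureMatrix, contact_only: bool = True) -> float:
    """Arithmetic mean pressure Pv in kPa.

    With ``contact_only=True`` (default) the mean is taken over cells at or
    above the contact threshold, so off-body sensor cells do not dilute the
    statistic; ``contact_only=False`` averages every cell.
    """
    if contact_only:
        vals = m.values[m.contact_mask]
        if vals.size == 0:
            raise NoContactError("no cells at or above the contact threshold")
        return float(vals.mean())
    return float(m.values.mean())


def peak_pressure(m: PressureMatrix) -> float:
    """Maximum pressure Pm in kPa over all cells."""
    return float(m.values.max())


def row_gradient_profile(m: PressureMatrix) -> np.ndarray:
    """Literal per-row gradient values.

    For each row ``i >= 1`` returns ``G_i = sum_j (p[i,j] - p[i-1,j]) / l``
    (signed); the result has ``rows - 1`` entries.
    """
    vals = m.values
    if vals.shape[0] < 2:
        raise ValueError("row gradient needs at least two rows")
    return np.diff(vals, axis=0).sum(axis=1) / m.pitch_cm


def pointwise_gradient_field(m: PressureMatrix) -> np.ndarray:
    """Per-cell central-difference gradient magnitude sqrt(gx^2 + gy^2)."""
    gy, gx = np.gradient(m.values, m.pitch_cm)
    return np.hypot(gx, gy)


def _gradient_values(m: PressureMatrix, mode: str, contact_only: bool) -> np.ndarray:
    if mode == "literal":
        return np.abs(row_gradient_profile(m))
    if mode == "pointwise":
        g = pointwise_gradient_field(m)
        if contact_only:
            vals = g[m.contact_mask]
            if vals.size == 0:
                raise NoContactError("no cells at or above the contact threshold")
            return vals
        return g.ravel()
    raise ValueError(f"unknown gradient mode {mode!r}")


def max_gradient(m: PressureMatrix, mode: str = "literal", contact_only: bool = True) -> float:
    """Maximum pressure gradient Gm for the chosen mode."""
    return float(_gradient_values(m, mode, contact_only).max())


def mean_gradient(m: PressureMatrix, mode: str = "literal", contact_only: bool = True) -> float:
    """Mean pressure gradient Gv for the chosen mode (mean of |G| values)."""
    return float(_gradient_values(m, mode, contact_only).mean())


def pressure_indices(
    m: PressureMatrix, mode: str = "literal", contact_only: bool = True
) -> PressureIndices:
    """All four indices of one matrix, using one gradient mode throughout."""
    return PressureIndices(
        Pv=average_pressure(m, contact_only=contact_only),
        Pm=peak_pressure(m),
        Gm=max_gradient(m, mode=mode, contact_only=contact_only),
        Gv=mean_gradient(m, mode=mode, contact_only=contact_only),
    )


def _partition_literal_gradients(
    vals: np.ndarray, mask: np.ndarray, pitch: float
) -> np.ndarray:
    """Literal row gradients restricted to within-partition cell pairs."""
    both = mask[1:, :] & mask[:-1, :]
    diffs = np.where(both, vals[1:, :] - vals[:-1, :], 0.0)
    rows_with_pairs = both.any(axis=1)
    if not rows_with_pairs.any():
        return np.zeros(1)
    return diffs[rows_with_pairs].sum(axis=1) / pitch


def partition_indices(
    m: PressureMatrix,
    pm: "PartitionMap",
    mode: str = "literal",
) -> Dict[str, PressureIndices]:
    """Per-partition indices: each index over that partition's cells only.

    Gradients are restricted to within-partition cell pairs (literal mode)
    or within-partition cells of the global central-difference field
    (pointwise mode). Raises :class:`NoContactError` for an empty partition.
    """
    if pm.labels.shape != m.shape:
        raise ValueError(
            f"partition map shape {pm.labels.shape} does not match matrix shape {m.shape}"
        )
    if mode == "pointwise":
        gfield = pointwise_gradient_field(m)
    out: Dict[str, PressureIndices] = {}
    for label, name in sorted(pm.names.items()):
        mask = pm.labels == label
        if not mask.any():
            raise NoContactError(f"partition {name!r} (label {label}) has no cells")
        vals = m.values[mask]
        if mode == "literal":
            grads = np.abs(_partition_literal_gradients(m.values, mask, m.pitch_cm))
        elif mode == "pointwise":
            grads = gfield[mask]
        else:
            raise ValueError(f"unknown gradient mode {mode!r}")
        out[name] = PressureIndices(
            Pv=float(vals.mean()),
            Pm=float(vals.max()),
            Gm=float(grads.max()),
            Gv=float(grads.mean()),
        )
    return out
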