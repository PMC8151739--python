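"""Ideal pressure-distribution matrix construction and matrix similarity.

The highest-comfort recordings approximate the support pattern a user
actually wants.  Trials of one posture are ranked by their subjective
comfort total, the top fraction (default 10%) is kept, each kept matrix is
aligned by translating its center of pressure to the grid center, and the
element-wise mean of the aligned matrices is the *ideal pressure
distribution matrix* for that posture.  Candidate surfaces are compared to
it with the cosine similarity of the flattened matrices, which is 1 exactly
when the two fields are positive scalar multiples of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import NoContactError, Posture, PressureMatrix, TrialRecord

__all__ = [
    "IdealMatrix",
    "rank_trials",
    "center_of_pressure",
    "align_to_center",
    "build_ideal_matrix",
    "cosine_similarity",
]


@dataclass(frozen=True)
class IdealMatrix:
    """Element-wise mean of the aligned top-comfort pressure matrices."""

    matrix: PressureMatrix
    posture: Posture
    source_trial_ids: Tuple[str, ...]
    fraction: float
    shifts: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must lie in (0, 1]")
        if len(self.source_trial_ids) < 1:
            raise ValueError("an ideal matrix needs at least one source trial")


def rank_trials(trials: Sequence[TrialRecord], posture: Posture | str) -> List[TrialRecord]:
    """Trials of one posture, descending by comfort total.

    Ties are broken by the higher minimum sub-score, then lexicographically
    by trial id, so the ordering is deterministic. Only ``emg_valid`` trials
    of the requested posture are considered.
    """
    posture = Posture.coerce(posture)
    pool = [t for t in trials if t.emg_valid and t.posture == posture]
    if not pool:
        raise ValueError(f"no valid trials with posture {posture.value!r}")
    return sorted(
        pool,
        key=lambda t: (-t.comfort.total, -min(t.comfort.subscores), t.trial_id),
    )


def center_of_pressure(m: PressureMatrix) -> Tuple[float, float]:
    """Pressure-weighted centroid (row, col) of the contact footprint."""
    vals = np.where(m.contact_mask, m.values, 0.0)
    total = vals.sum()
    if total <= 0:
        raise NoContactError("cannot compute center of pressure of an empty footprint")
    rows, cols = np.indices(vals.shape)
    return float((rows * vals).sum() / total), float((cols * vals).sum() / total)


def align_to_center(m: PressureMatrix) -> Tuple[PressureMatrix, Tuple[int, int]]:
    """Shift the matrix by whole cells so its center of pressure sits at the
    grid center; vacated cells are zero-filled. Returns (shifted, (dr, dc))."""
    r, c = center_of_pressure(m)
    # integer center cell, so same-template recordings get identical shifts
    target = (m.shape[0] // 2, m.shape[1] // 2)
    dr, dc = int(round(target[0] - r)), int(round(target[1] - c))
    shifted = np.zeros_like(m.values)
    src = m.values
    r0, r1 = max(0, dr), min(src.shape[0], src.shape[0] + dr)
    c0, c1 = max(0, dc), min(src.shape[1], src.shape[1] + dc)
    shifted[r0:r1, c0:c1] = src[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return m.with_values(shifted), (dr, dc)


def _n_keep(n: int, fraction: float, min_keep: int, round_mode: str) -> int:
    if round_mode == "floor":
        k = math.floor(fraction * n)
    elif round_mode == "ceil":
        k = math.ceil(fraction * n)
    else:
        raise ValueError(f"round_mode must be 'floor' or 'ceil', got {round_mode!r}")
    return min(n, max(min_keep, k))


def build_ideal_matrix(
    trials: Sequence[TrialRecord],
    fraction: float = 0.10,
    min_keep: int = 1,
    round_mode: str = "floor",
    align: bool = True,
    posture: Optional[Posture | str] = None,
) -> IdealMatrix:
    """Average the top-comfort fraction of a posture's trials.

    ``round_mode`` controls how ``fraction * n`` is rounded to a trial count
    (floor by default, with a floor of ``min_keep``). With ``align=True``
    each kept matrix is first shifted so its center of pressure coincides
    with the grid center, so anatomically corresponding peaks average
    coherently instead of blurring.
    """
    if posture is None:
        postures = {t.posture for t in trials}
        if len(postures) != 1:
            raise ValueError("trials mix postures; pass posture= explicitly")
        posture = postures.pop()
    posture = Posture.coerce(posture)
    ranked = rank_trials(trials, posture)
    keep = ranked[: _n_keep(len(ranked), fraction, min_keep, round_mode)]

    shapes = {t.matrix.shape for t in keep}
    pitches = {t.matrix.pitch_cm for t in keep}
    if len(shapes) > 1 or len(pitches) > 1:
        bad = ", ".join(t.trial_id for t in keep)
        raise ValueError(f"kept trials have mismatched grids or pitches: {bad}")

    shifts: List[Tuple[int, int]] = []
    stack = []
    for t in keep:
        if align:
            shifted, shift = align_to_center(t.matrix)
        else:
            shifted, shift = t.matrix, (0, 0)
        shifts.append(shift)
        stack.append(shifted.values)
    mean = np.mean(stack, axis=0)
    ref = keep[0].matrix
    return IdealMatrix(
        matrix=PressureMatrix(mean, ref.pitch_cm, ref.contact_threshold_kpa),
        posture=posture,
        source_trial_ids=tuple(t.trial_id for t in keep),
        fraction=fraction,
        shifts=tuple(shifts),
    )


def cosine_similarity(a: PressureMatrix | np.ndarray, b: PressureMatrix | np.ndarray) -> float:
    """Cosine similarity of two same-shape matrices, flattened.

    ``sum(A_i B_i) / (||A|| ||B||)``; lies in [0, 1] for non-negative
    fields and equals 1 exactly for positive scalar multiples.
    """
    va = a.values if isinstance(a, PressureMatrix) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, PressureMatrix) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise NoContactError("cosine similarity undefined for an all-zero matrix")
    return float(np.vdot(va, vb) / (na * nb))
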