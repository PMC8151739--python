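"""Fuzzy analytic hierarchy process (FAHP) partition sensitivity weights.

Different head/neck regions tolerate pressure very differently (bony,
muscular and vascular tissue under the skin), so each support partition
gets a *pressure sensitivity weight*: how precisely its ideal pressure must
be reproduced, and how much it counts in the overall comfort score.

Experts compare partitions pairwise on a nine-level strength scale (9 =
far more sensitive).  The pair strengths are converted to a *complementary*
judgment matrix (``V_ii = 0.5``, ``V_ij + V_ji = 1``) via
``V_ij = a_ij / (a_ij + a_ji)``, from which the row-sum formula

    ``W_i = (sum_j V_ij + n/2 - 1) / (n (n - 1))``

yields weights that sum to exactly 1 (an algebraic identity of the
complementary constraint).  A two-level hierarchy (posture layer over
partition layer) is combined multiplicatively, and a multi-expert panel is
aggregated by averaging the per-expert weights.

Consistency: a complementary matrix is additively consistent iff
``V_ij = 0.5 + (n - 1)(W_i - W_j)`` with the row-sum weights above; the
compatibility index reported here is the mean absolute deviation from that
reconstruction over the strict upper triangle (x 2/(n(n-1))), with a
conventional pass threshold of 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "JudgmentMatrix",
    "WeightVector",
    "ConsistencyResult",
    "to_complementary",
    "fahp_weights",
    "consistency_check",
    "combine_hierarchy",
    "aggregate_experts",
]

NINE_LEVEL = "nine_level"
COMPLEMENTARY = "complementary"


@dataclass(frozen=True)
class JudgmentMatrix:
    """Pairwise comparison matrix over a set of labeled items.

    ``nine_level``: ``entries[i, j]`` is the 1..9 strength of item i over
    item j (both directions stored; indifference is (k, k)).
    ``complementary``: ``entries`` satisfies ``V_ii = 0.5`` and
    ``V_ij + V_ji = 1`` with all values in [0, 1].
    """

    entries: np.ndarray
    labels: Tuple[str, ...]
    scale: str = NINE_LEVEL
    expert_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=float).copy()
        n = len(self.labels)
        if arr.shape != (n, n):
            raise ValueError(f"entries shape {arr.shape} does not match {n} labels")
        if n < 2:
            raise ValueError("need at least two items to compare")
        if self.scale == NINE_LEVEL:
            off = ~np.eye(n, dtype=bool)
            if np.any(arr[off] < 1) or np.any(arr[off] > 9):
                raise ValueError("nine-level entries must lie in 1..9")
        elif self.scale == COMPLEMENTARY:
            bad = _complementary_violation(arr)
            if bad is not None:
                i, j = bad
                raise ValueError(
                    f"matrix is not complementary at cell ({i}, {j}): "
                    f"V_ij={arr[i, j]:.4f}, V_ji={arr[j, i]:.4f}"
                )
        else:
            raise ValueError(f"unknown scale {self.scale!r}")
        arr.setflags(write=False)
        object.__setattr__(self, "entries", arr)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)


def _complementary_violation(arr: np.ndarray, tol: float = 1e-9) -> Optional[Tuple[int, int]]:
    n = arr.shape[0]
    for i in range(n):
        if abs(arr[i, i] - 0.5) > tol:
            return (i, i)
        for j in range(i + 1, n):
            if abs(arr[i, j] + arr[j, i] - 1.0) > tol:
                return (i, j)
            if not (-tol <= arr[i, j] <= 1 + tol):
                return (i, j)
    return None


@dataclass(frozen=True)
class WeightVector:
    """Normalized weights over labeled items (sum to 1, all positive)."""

    weights: Dict[str, float]
    level: str = "C"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("empty weight vector")
        vals = np.array(list(self.weights.values()), dtype=float)
        if np.any(vals <= 0):
            raise ValueError("all weights must be positive")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {vals.sum():.12f})")
        object.__setattr__(self, "weights", dict(self.weights))

    def __getitem__(self, label: str) -> float:
        return self.weights[label]

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(self.weights)

    def as_array(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        order = order or self.labels
        return np.array([self.weights[l] for l in order], dtype=float)


@dataclass(frozen=True)
class ConsistencyResult:
    index: float
    threshold: float

    @property
    def passed(self) -> bool:
        return self.index <= self.threshold


def to_complementary(nine_level: JudgmentMatrix) -> JudgmentMatrix:
    """Convert 1..9 pair strengths to a complementary matrix.

    ``V_ij = a_ij / (a_ij + a_ji)`` preserves the ordering of the pair,
    maps indifference to 0.5 and is reciprocal-consistent by construction.
    """
    if nine_level.scale != NINE_LEVEL:
        raise ValueError("input must be a nine-level matrix")
    a = nine_level.entries
    v = a / (a + a.T)
    np.fill_diagonal(v, 0.5)
    return JudgmentMatrix(v, nine_level.labels, COMPLEMENTARY, nine_level.expert_id)


def fahp_weights(mc: JudgmentMatrix, level: str = "C") -> WeightVector:
    """Row-sum weights of a complementary judgment matrix.

    ``W_i = (sum_j V_ij + n/2 - 1) / (n (n - 1))``; the weights sum to 1
    for any complementary matrix.
    """
    if mc.scale != COMPLEMENTARY:
        raise ValueError("fahp_weights needs a complementary matrix; use to_complementary first")
    n = mc.n
    w = (mc.entries.sum(axis=1) + n / 2.0 - 1.0) / (n * (n - 1.0))
    return WeightVector(dict(zip(mc.labels, (float(x) for x in w))), level=level)


def consistency_check(
    mc: JudgmentMatrix, w: WeightVector, threshold: float = 0.1
) -> ConsistencyResult:
    """Compatibility index of a complementary matrix against its weights.

    ``CI = 2/(n(n-1)) * sum_{i<j} |V_ij - (0.5 + (n-1)(W_i - W_j))|``;
    CI = 0 exactly for an additively consistent matrix and the check passes
    when CI <= threshold.
    """
    if mc.scale != COMPLEMENTARY:
        raise ValueError("consistency_check needs a complementary matrix")
    n = mc.n
    wv = w.as_array(mc.labels)
    recon = 0.5 + (n - 1.0) * (wv[:, None] - wv[None, :])
    iu = np.triu_indices(n, k=1)
    ci = float(np.abs(mc.entries[iu] - recon[iu]).sum() * 2.0 / (n * (n - 1.0)))
    return ConsistencyResult(index=ci, threshold=threshold)


def combine_hierarchy(
    wb: WeightVector, wc_groups: Mapping[str, WeightVector]
) -> WeightVector:
    """Final weights of a two-level hierarchy.

    The middle layer ``wb`` weights the groups (here: postures); each group
    has its own bottom-layer vector. The final weight of item i in group g
    is ``WB_g * WC_{g,i}``, and the final vector sums to 1 whenever the
    inputs do.
    """
    if set(wb.labels) != set(wc_groups):
        raise ValueError(
            f"group mismatch: middle layer has {sorted(wb.labels)}, "
            f"bottom layers given for {sorted(wc_groups)}"
        )
    final: Dict[str, float] = {}
    for g in wb.labels:
        for label, wc in wc_groups[g].weights.items():
            if label in final:
                raise ValueError(f"duplicate item label {label!r} across groups")
            final[label] = wb[g] * wc
    return WeightVector(final, level="final")


def aggregate_experts(per_expert: Sequence[WeightVector]) -> WeightVector:
    """Average a panel's weight vectors per item and renormalize."""
    if not per_expert:
        raise ValueError("empty expert panel")
    keys = set(per_expert[0].labels)
    for wv in per_expert[1:]:
        if set(wv.labels) != keys:
            raise ValueError("experts rated different partition sets")
    order = list(per_expert[0].labels)
    mean = np.mean([wv.as_array(order) for wv in per_expert], axis=0)
    mean = mean / mean.sum()
    return WeightVector(dict(zip(order, (float(x) for x in mean))), level=per_expert[0].level)
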