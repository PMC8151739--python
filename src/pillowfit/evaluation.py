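"""Weighted comfort scoring and prototype evaluation.

Two complementary views of how well a candidate surface reproduces the
ideal support:

* per-partition: the four pressure indices of each partition compared with
  their ideal targets (deltas = measured - ideal);
* whole-matrix: cosine similarity between the candidate's pressure matrix
  and the ideal matrix.

When per-partition subjective ratings are available, the overall comfort
is their weighted sum ``sum_i x_i w_i`` with the partition sensitivity
weights; otherwise the weighted score is omitted rather than imputed.
Across a cohort, the agreement between similarity ranking and subjective
totals is summarized as a Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import PressureIndices, PressureMatrix, TrialRecord, partition_indices
from .fahp import WeightVector
from .ideal import IdealMatrix, cosine_similarity
from .segmentation import PartitionMap

__all__ = [
    "EvaluationReport",
    "weighted_comfort",
    "evaluate_prototype",
    "similarity_comfort_consistency",
]


def weighted_comfort(x: Mapping[str, float], w: WeightVector) -> float:
    """Weighted comfort ``sum_i x_i w_i`` over shared partition labels.

    ``w`` must be normalized, so the score is a convex combination of the
    per-partition ratings and lies within their range.
    """
    if set(x) != set(w.labels):
        raise ValueError(
            f"rating labels {sorted(x)} do not match weight labels {sorted(w.labels)}"
        )
    return float(sum(x[l] * w[l] for l in w.labels))


@dataclass(frozen=True)
class EvaluationReport:
    """Evaluation of one trial against the ideal support model."""

    trial_id: str
    similarity: float
    per_partition_indices: Dict[str, Dict[str, PressureIndices]]  # name -> measured/ideal
    deltas: Dict[str, Dict[str, float]]  # name -> index -> measured - ideal
    weighted_comfort: Optional[float] = None
    subjective_total: Optional[int] = None

    def flat_rows(self) -> List[Dict[str, object]]:
        """One row per partition, for CSV export."""
        rows = []
        for name, pair in self.per_partition_indices.items():
            row: Dict[str, object] = {
                "trial_id": self.trial_id,
                "partition": name,
                "similarity": self.similarity,
                "weighted_comfort": self.weighted_comfort,
                "subjective_total": self.subjective_total,
            }
            for idx in ("Pv", "Pm", "Gm", "Gv"):
                row[f"{idx}_measured"] = getattr(pair["measured"], idx)
                row[f"{idx}_ideal"] = getattr(pair["ideal"], idx)
                row[f"{idx}_delta"] = self.deltas[name][idx]
            rows.append(row)
        return rows


def evaluate_prototype(
    trials: Sequence[TrialRecord],
    ideal: IdealMatrix,
    pm: PartitionMap,
    w: Optional[WeightVector] = None,
    ideal_targets: Optional[Mapping[str, PressureIndices]] = None,
    ratings: Optional[Mapping[str, Mapping[str, float]]] = None,
    gradient_mode: str = "pointwise",
    align: bool = True,
) -> List[EvaluationReport]:
    """Evaluate trials against the ideal model; best similarity first.

    With ``align=True`` each trial matrix is first shifted so its center of
    pressure sits at the grid center — the same canonical frame the ideal
    matrix and partition map live in — before similarity and per-partition
    indices are computed.  ``ideal_targets`` defaults to the packaged ideal
    per-partition index table where the partition names match it, falling
    back to indices computed from the ideal matrix itself for any other
    name.  ``ratings`` optionally maps trial_id -> partition -> subjective
    rating; the weighted comfort is only computed where ratings (and ``w``)
    are given.
    """
    from . import reference
    from .ideal import align_to_center

    self_targets = partition_indices(ideal.matrix, pm, mode=gradient_mode)
    targets: Dict[str, PressureIndices] = {}
    for name in self_targets:
        if ideal_targets is not None and name in ideal_targets:
            targets[name] = ideal_targets[name]
        elif ideal_targets is None and name in reference.IDEAL_PARTITION_INDICES:
            targets[name] = reference.IDEAL_PARTITION_INDICES[name]
        else:
            targets[name] = self_targets[name]

    reports: List[EvaluationReport] = []
    for t in trials:
        if t.matrix.shape != ideal.matrix.shape:
            raise ValueError(
                f"trial {t.trial_id} grid {t.matrix.shape} does not match "
                f"ideal grid {ideal.matrix.shape}"
            )
        tm = align_to_center(t.matrix)[0] if align else t.matrix
        measured = partition_indices(tm, pm, mode=gradient_mode)
        per_part = {
            name: {"measured": measured[name], "ideal": targets[name]} for name in measured
        }
        deltas = {name: measured[name].delta(targets[name]) for name in measured}
        score = None
        if w is not None and ratings is not None and t.trial_id in ratings:
            score = weighted_comfort(ratings[t.trial_id], w)
        reports.append(
            EvaluationReport(
                trial_id=t.trial_id,
                similarity=cosine_similarity(tm, ideal.matrix),
                per_partition_indices=per_part,
                deltas=deltas,
                weighted_comfort=score,
                subjective_total=t.comfort.total,
            )
        )
    reports.sort(key=lambda r: (-r.similarity, r.trial_id))
    return reports


def similarity_comfort_consistency(reports: Sequence[EvaluationReport]) -> float:
    """Spearman rank correlation between similarity and subjective totals."""
    pairs = [(r.similarity, r.subjective_total) for r in reports if r.subjective_total is not None]
    if len(pairs) < 3:
        raise ValueError("need at least three rated trials for a rank correlation")
    sim, tot = zip(*pairs)
    rho = stats.spearmanr(sim, tot).statistic
    return float(rho)
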