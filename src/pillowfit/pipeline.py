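"""End-to-end orchestration: simulate -> ideal -> partition -> weights ->
design -> evaluate.

A run consumes a :class:`PipelineConfig`, executes every stage for both
postures, and writes all artifacts (cohort matrices + manifest, ideal
matrices with provenance, partition maps, weight tables, per-partition
ideal index tables, pore layouts, evaluation reports) plus a machine-
readable run summary into one directory.  All stochastic stages consume
seeds derived from the single run seed, so a rerun with the same config
is numerically identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io, reference
from .core import Posture, partition_indices
from .design import ElasticCalibration, compressed_geometry, pore_layout
from .evaluation import evaluate_prototype, similarity_comfort_consistency
from .fahp import (
    WeightVector,
    aggregate_experts,
    combine_hierarchy,
    consistency_check,
    fahp_weights,
    to_complementary,
)
from .ideal import build_ideal_matrix
from .segmentation import fcm, label_map, name_partitions
from .simulate import (
    GeneratorConfig,
    generate_contour_nodes,
    generate_expert_panel,
    generate_trial_cohort,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "partition_weights_from_panels"]

# middle-layer (posture) sensitivities implied by the per-partition table
_POSTURE_SENSITIVITY = {
    "supine": sum(reference.PARTITION_SENSITIVITY_WEIGHTS[p] for p in reference.SUPINE_PARTITIONS),
    "lateral": sum(reference.PARTITION_SENSITIVITY_WEIGHTS[p] for p in reference.LATERAL_PARTITIONS),
}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "runs/run0"
    seed: int = 42
    fraction: float = 0.10
    round_mode: str = "floor"
    align: bool = True
    fcm_c: int = 3
    fcm_m: float = 2.0
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300
    gradient_mode: str = "pointwise"
    consistency_threshold: float = 0.1
    n_experts: int = 10
    expert_noise_sd: float = 0.5
    group: str = "MS"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in data.pop("generator", {}).items()})
        return cls(generator=gen, **data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    ideals: Dict[str, object]
    partition_maps: Dict[str, object]
    weights: WeightVector
    ideal_indices: Dict[str, Dict[str, object]]
    geometry: Dict[str, object]
    layouts: Dict[str, object]
    reports: Dict[str, list]
    summary: dict


def partition_weights_from_panels(
    config: PipelineConfig, seed: int
) -> Tuple[WeightVector, List[dict]]:
    """Expert-panel FAHP weights through the two-level hierarchy.

    Each expert judges the posture pair (middle layer) and the partitions
    within each posture (bottom layers); the per-expert final vectors are
    averaged.  Returns the aggregated weights and per-matrix consistency
    notes.
    """
    notes: List[dict] = []
    group_sens = {
        "supine": {p: reference.PARTITION_SENSITIVITY_WEIGHTS[p] for p in reference.SUPINE_PARTITIONS},
        "lateral": {p: reference.PARTITION_SENSITIVITY_WEIGHTS[p] for p in reference.LATERAL_PARTITIONS},
    }
    b_panel = generate_expert_panel(
        config.n_experts, _POSTURE_SENSITIVITY, config.expert_noise_sd, seed
    )
    c_panels = {
        posture: generate_expert_panel(
            config.n_experts, sens, config.expert_noise_sd, seed + 1 + k
        )
        for k, (posture, sens) in enumerate(group_sens.items())
    }
    finals: List[WeightVector] = []
    for e in range(config.n_experts):
        mb = to_complementary(b_panel[e])
        wb = fahp_weights(mb, level="B")
        cons = consistency_check(mb, wb, config.consistency_threshold)
        if not cons.passed:
            notes.append({"expert": e + 1, "matrix": "posture", "ci": cons.index})
        wcs: Dict[str, WeightVector] = {}
        for posture in group_sens:
            mc = to_complementary(c_panels[posture][e])
            wc = fahp_weights(mc)
            cons = consistency_check(mc, wc, config.consistency_threshold)
            if not cons.passed:
                notes.append({"expert": e + 1, "matrix": posture, "ci": cons.index})
            wcs[posture] = wc
        finals.append(combine_hierarchy(wb, wcs))
    return aggregate_experts(finals), notes


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage for both postures and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: Dict[str, float] = {}
    warnings_log: List[str] = []

    # simulate
    gen = GeneratorConfig(**{**asdict(config.generator), "seed": config.seed})
    cohorts = {}
    for k, posture in enumerate(("supine", "lateral")):
        cohorts[posture] = generate_trial_cohort(gen, posture, seed=config.seed + 10 * k)
        io.write_cohort(out / f"cohort_{posture}", cohorts[posture])
    timings["simulate"] = time.time() - t0

    # ideal matrices
    t = time.time()
    ideals = {}
    for posture, trials in cohorts.items():
        ideals[posture] = build_ideal_matrix(
            trials,
            fraction=config.fraction,
            round_mode=config.round_mode,
            align=config.align,
            posture=posture,
        )
        io.write_ideal(out, ideals[posture])
    timings["ideal"] = time.time() - t

    # partition
    t = time.time()
    pms = {}
    for posture, ideal in ideals.items():
        m = ideal.matrix
        result = fcm(
            m.values[m.contact_mask],
            c=config.fcm_c,
            m_fuzz=config.fcm_m,
            tol=config.fcm_tol,
            max_iter=config.fcm_max_iter,
            seed=config.seed,
        )
        if not result.converged:
            warnings_log.append(f"FCM did not converge for {posture} ideal matrix")
        pm = name_partitions(label_map(result, m), posture, matrix=m, strict=False)
        pms[posture] = pm
        io.write_partition_map(out, pm, f"partition_{posture}")
    timings["partition"] = time.time() - t

    # ideal per-partition indices
    t = time.time()
    ideal_idx = {}
    for posture, ideal in ideals.items():
        idx = partition_indices(ideal.matrix, pms[posture], mode=config.gradient_mode)
        ideal_idx[posture] = idx
        pd.DataFrame(
            [
                {"partition": name, "Pv": v.Pv, "Pm": v.Pm, "Gm": v.Gm, "Gv": v.Gv}
                for name, v in idx.items()
            ]
        ).to_csv(out / f"ideal_indices_{posture}.csv", index=False)
    timings["indices"] = time.time() - t

    # weights
    t = time.time()
    weights, notes = partition_weights_from_panels(config, config.seed + 100)
    for n in notes:
        warnings_log.append(
            f"consistency check failed: expert {n['expert']} {n['matrix']} CI={n['ci']:.3f}"
        )
    io.write_weights(out / "partition_weights.csv", weights)
    timings["weights"] = time.time() - t

    # material design
    t = time.time()
    cal = ElasticCalibration.from_reference()
    io.write_calibration(out / "calibration.csv", cal)
    geometry, layouts = {}, {}
    for posture, ideal in ideals.items():
        geo = compressed_geometry(
            _nodes_for(pms[posture], config, seed=config.seed + 200),
            ideal,
            pms[posture],
        )
        geometry[posture] = geo
        layout = pore_layout(geo, pms[posture], cal, pitch_cm=gen.pitch_cm)
        if any(h.clamped for h in layout.holes):
            clamped = sorted({h.partition for h in layout.holes if h.clamped})
            warnings_log.append(f"{posture}: pore diameters clamped for partitions {clamped}")
        layouts[posture] = layout
        io.write_pore_layout(out / f"pore_layout_{posture}_{config.group}.csv", layout)
        io.write_point_list(out / f"pore_layout_{posture}_{config.group}.txt", layout)
        rows = [
            {
                "partition": name,
                "force_N": e.total_force_n,
                "dH_mm": e.height_change_mm,
                "compressed_height_mm": e.compressed_height_mm,
                "required_k": e.required_k,
            }
            for name, e in geo.entries.items()
        ]
        pd.DataFrame(rows).to_csv(out / f"geometry_{posture}_{config.group}.csv", index=False)
    timings["design"] = time.time() - t

    # evaluate
    t = time.time()
    reports = {}
    spearman = {}
    for posture, trials in cohorts.items():
        reps = evaluate_prototype(
            trials, ideals[posture], pms[posture], w=None, gradient_mode=config.gradient_mode
        )
        reports[posture] = reps
        io.write_reports(out / f"evaluation_{posture}.csv", reps)
        spearman[posture] = similarity_comfort_consistency(reps)
    timings["evaluate"] = time.time() - t

    summary = {
        "config": config.to_dict(),
        "partitions": {p: sorted(pms[p].names.values()) for p in pms},
        "n_partitions_total": sum(len(pms[p].names) for p in pms),
        "weights": dict(weights.weights),
        "similarity_comfort_spearman": spearman,
        "warnings": warnings_log,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return PipelineResult(
        out_dir=out,
        ideals=ideals,
        partition_maps=pms,
        weights=weights,
        ideal_indices=ideal_idx,
        geometry=geometry,
        layouts=layouts,
        reports=reports,
        summary=summary,
    )


def _nodes_for(pm, config: PipelineConfig, seed: int):
    """Contour nodes covering exactly this partition map's names.

    Extra (suffixed) partition names inherit the base partition's node.
    """
    from .design import ContourNodes
    from .simulate import _BASE_NODES, generate_contour_nodes

    base = generate_contour_nodes(config.group, seed=seed)
    nodes = {}
    for name in pm.names.values():
        key = name if name in base.nodes else name[:2]
        if key not in base.nodes:
            raise ValueError(f"no contour node for partition {name!r}")
        nodes[name] = base.nodes[key]
    return ContourNodes(group=base.group, nodes=nodes)
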