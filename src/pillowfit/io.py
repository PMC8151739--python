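"""Plain-text file formats for matrices, manifests, maps and tables.

* Pressure matrices: delimited text (comma or tab), one sensor row per
  line, values in kPa.
* Trial manifest: JSON; one entry per recording with the matrix filename,
  pillow/subject ids, posture, sensor pitch, the four comfort sub-scores
  and the EMG validity flag.
* Partition maps: integer grid in the same delimited format plus a JSON
  name table.
* Judgment matrices, weight vectors, calibrations, layouts, reports: CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ComfortScore, Posture, PressureMatrix, TrialRecord
from .design import ElasticCalibration, PartitionGeometry, PoreLayout
from .evaluation import EvaluationReport
from .fahp import COMPLEMENTARY, NINE_LEVEL, JudgmentMatrix, WeightVector
from .ideal import IdealMatrix
from .segmentation import PartitionMap

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_cohort",
    "read_cohort",
    "write_ideal",
    "read_ideal",
    "write_partition_map",
    "read_partition_map",
    "read_judgment_matrix",
    "write_weights",
    "read_weights",
    "write_calibration",
    "read_calibration",
    "write_pore_layout",
    "write_point_list",
    "write_reports",
    "render_partition_map",
]


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0]
    return "\t" if "\t" in first else ","


def read_matrix(
    path: str | Path, pitch_cm: float = 1.1, contact_threshold_kpa: float = 0.1
) -> PressureMatrix:
    path = Path(path)
    values = np.loadtxt(path, delimiter=_sniff_delimiter(path))
    return PressureMatrix(values, pitch_cm, contact_threshold_kpa)


def write_matrix(path: str | Path, m: PressureMatrix | np.ndarray, delimiter: str = ",") -> None:
    values = m.values if isinstance(m, PressureMatrix) else np.asarray(m)
    np.savetxt(path, values, fmt="%.6g", delimiter=delimiter)


def write_cohort(directory: str | Path, trials: Sequence[TrialRecord]) -> Path:
    """Write matrix files plus a trial manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for t in trials:
        fname = f"{t.posture.value}_{t.pillow_id}_{t.subject_id}.csv"
        write_matrix(directory / fname, t.matrix)
        entries.append(
            {
                "matrix_file": fname,
                "pillow_id": t.pillow_id,
                "subject_id": t.subject_id,
                "posture": t.posture.value,
                "pitch_cm": t.matrix.pitch_cm,
                "contact_threshold_kpa": t.matrix.contact_threshold_kpa,
                "comfort": {
                    "softness": t.comfort.softness,
                    "wrapping": t.comfort.wrapping,
                    "support": t.comfort.support,
                    "fit": t.comfort.fit,
                },
                "emg_valid": t.emg_valid,
            }
        )
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"trials": entries}, indent=2))
    return manifest


def read_cohort(directory: str | Path) -> List[TrialRecord]:
    directory = Path(directory)
    manifest = directory / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(f"no trial manifest at {manifest}")
    data = json.loads(manifest.read_text())
    trials = []
    for e in data["trials"]:
        m = read_matrix(
            directory / e["matrix_file"],
            pitch_cm=e.get("pitch_cm", 1.1),
            contact_threshold_kpa=e.get("contact_threshold_kpa", 0.1),
        )
        trials.append(
            TrialRecord(
                pillow_id=e["pillow_id"],
                subject_id=e["subject_id"],
                posture=Posture(e["posture"]),
                matrix=m,
                comfort=ComfortScore(**e["comfort"]),
                emg_valid=bool(e.get("emg_valid", True)),
            )
        )
    return trials


def write_ideal(directory: str | Path, ideal: IdealMatrix, stem: Optional[str] = None) -> Path:
    """Ideal matrix + provenance (source ids, fraction, alignment shifts)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"ideal_{ideal.posture.value}"
    write_matrix(directory / f"{stem}.csv", ideal.matrix)
    prov = {
        "posture": ideal.posture.value,
        "fraction": ideal.fraction,
        "source_trial_ids": list(ideal.source_trial_ids),
        "alignment_shifts": [list(s) for s in ideal.shifts],
        "pitch_cm": ideal.matrix.pitch_cm,
        "contact_threshold_kpa": ideal.matrix.contact_threshold_kpa,
    }
    (directory / f"{stem}.provenance.json").write_text(json.dumps(prov, indent=2))
    return directory / f"{stem}.csv"


def read_ideal(directory: str | Path, stem: str) -> IdealMatrix:
    directory = Path(directory)
    prov = json.loads((directory / f"{stem}.provenance.json").read_text())
    m = read_matrix(
        directory / f"{stem}.csv",
        pitch_cm=prov["pitch_cm"],
        contact_threshold_kpa=prov["contact_threshold_kpa"],
    )
    return IdealMatrix(
        matrix=m,
        posture=Posture(prov["posture"]),
        source_trial_ids=tuple(prov["source_trial_ids"]),
        fraction=prov["fraction"],
        shifts=tuple(tuple(s) for s in prov["alignment_shifts"]),
    )


def write_partition_map(directory: str | Path, pm: PartitionMap, stem: str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / f"{stem}.csv", pm.labels, fmt="%d", delimiter=",")
    meta = {
        "names": {str(k): v for k, v in pm.names.items()},
        "posture": pm.posture.value if pm.posture else None,
    }
    (directory / f"{stem}.names.json").write_text(json.dumps(meta, indent=2))
    return directory / f"{stem}.csv"


def read_partition_map(directory: str | Path, stem: str) -> PartitionMap:
    directory = Path(directory)
    labels = np.loadtxt(directory / f"{stem}.csv", delimiter=",", dtype=int)
    meta = json.loads((directory / f"{stem}.names.json").read_text())
    posture = Posture(meta["posture"]) if meta.get("posture") else None
    return PartitionMap(labels, {int(k): v for k, v in meta["names"].items()}, posture)


def read_judgment_matrix(
    path: str | Path, labels: Sequence[str], scale: str = NINE_LEVEL, expert_id: str = ""
) -> JudgmentMatrix:
    path = Path(path)
    entries = np.loadtxt(path, delimiter=_sniff_delimiter(path))
    return JudgmentMatrix(entries, tuple(labels), scale, expert_id)


def write_weights(path: str | Path, w: WeightVector) -> None:
    pd.DataFrame(
        {"partition": list(w.labels), "weight": [w[l] for l in w.labels]}
    ).to_csv(path, index=False)


def read_weights(path: str | Path, level: str = "final") -> WeightVector:
    df = pd.read_csv(path)
    return WeightVector(dict(zip(df["partition"], df["weight"])), level=level)


def write_calibration(path: str | Path, cal: ElasticCalibration) -> None:
    pd.DataFrame(cal.pairs, columns=["d_mm", "k"]).to_csv(path, index=False)


def read_calibration(path: str | Path) -> ElasticCalibration:
    df = pd.read_csv(path)
    return ElasticCalibration.fit(list(zip(df["d_mm"], df["k"])))


def write_pore_layout(path: str | Path, layout: PoreLayout) -> None:
    pd.DataFrame(
        [
            {
                "x_mm": h.x_mm,
                "y_mm": h.y_mm,
                "d_mm": h.diameter_mm,
                "partition": h.partition,
                "clamped": h.clamped,
            }
            for h in layout.holes
        ]
    ).to_csv(path, index=False)


def write_point_list(path: str | Path, layout: PoreLayout) -> None:
    """DXF-like plain-text point list (one ``x y diameter`` line per hole)
    for CAD import."""
    lines = [f"{h.x_mm:.3f} {h.y_mm:.3f} {h.diameter_mm:.3f}" for h in layout.holes]
    Path(path).write_text("\n".join(lines) + "\n")


def write_reports(path: str | Path, reports: Sequence[EvaluationReport]) -> None:
    rows = [row for r in reports for row in r.flat_rows()]
    pd.DataFrame(rows).to_csv(path, index=False)


def render_partition_map(path: str | Path, pm: PartitionMap) -> None:
    """Optional indexed-image rendering for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(pm.labels, interpolation="nearest", cmap="tab10")
    for label, name in pm.names.items():
        mask = pm.labels == label
        if mask.any():
            r, c = np.argwhere(mask).mean(axis=0)
            ax.text(c, r, name, ha="center", va="center", fontsize=9)
    ax.set_title(pm.posture.value if pm.posture else "partition map")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
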