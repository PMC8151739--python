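"""Packaged reference tables for the partitioned support model.

Small published/measured constants the pipeline uses as defaults:

* the pore-diameter vs. equivalent-elastic-coefficient calibration measured
  on 110 mm, 60 D memory foam with a 30 mm staggered hole pitch (disc
  indenter), and the power-law coefficients fitted from it;
* the ideal per-partition pressure indices for the seven partitions
  (supine A1-A3, lateral B1-B4);
* the expert-panel pressure-sensitivity weights per partition;
* the key ergonomic node associated with each partition;
* the anthropometric groups used for prototype sizing (male/female x
  small/large physique) with their mean stature;
* the per-partition equivalent-stiffness verification for the small-male
  prototype (calculated vs. actually measured k, relative error as printed
  in the verification report).
"""

from __future__ import annotations

from .core import PressureIndices

# (pore diameter mm, equivalent elastic coefficient k in N/mm)
ELASTIC_CALIBRATION_PAIRS = (
    (6.0, 0.541),
    (9.0, 0.302),
    (12.0, 0.191),
    (15.0, 0.152),
    (18.0, 0.122),
    (21.0, 0.113),
)

# d = a * k^b, valid for 6 <= d <= 21 mm
POWER_LAW_A = 3.613
POWER_LAW_B = -0.769
VALID_D_RANGE_MM = (6.0, 21.0)
FOAM_HEIGHT_MM = 110.0
HOLE_PITCH_MM = 30.0

SUPINE_PARTITIONS = ("A1", "A2", "A3")
LATERAL_PARTITIONS = ("B1", "B2", "B3", "B4")
ALL_PARTITIONS = SUPINE_PARTITIONS + LATERAL_PARTITIONS

PARTITION_DESCRIPTIONS = {
    "A1": "posterior neck area",
    "A2": "occipital area",
    "A3": "posterior parietal area",
    "B1": "cervical area",
    "B2": "jaw area",
    "B3": "temporal bone area",
    "B4": "lateral parietal area",
}

# ideal per-partition body-pressure indices (Pv, Pm kPa; Gm, Gv kPa/cm^2)
IDEAL_PARTITION_INDICES = {
    "A1": PressureIndices(Pv=1.94, Pm=7.04, Gm=2.16, Gv=0.21),
    "A2": PressureIndices(Pv=3.23, Pm=8.72, Gm=3.57, Gv=0.29),
    "A3": PressureIndices(Pv=1.24, Pm=4.68, Gm=1.77, Gv=0.22),
    "B1": PressureIndices(Pv=2.89, Pm=7.14, Gm=1.92, Gv=0.23),
    "B2": PressureIndices(Pv=1.86, Pm=5.19, Gm=1.71, Gv=0.21),
    "B3": PressureIndices(Pv=3.04, Pm=8.26, Gm=2.36, Gv=0.36),
    "B4": PressureIndices(Pv=1.47, Pm=5.12, Gm=1.93, Gv=0.29),
}

# expert-panel pressure-sensitivity weights (sum to 1 over all 7 partitions)
PARTITION_SENSITIVITY_WEIGHTS = {
    "A1": 0.146,
    "A2": 0.092,
    "A3": 0.082,
    "B1": 0.151,
    "B2": 0.182,
    "B3": 0.213,
    "B4": 0.134,
}

# mean pressure gradient band associated with comfortable support (kPa/cm^2)
COMFORT_GV_BAND = (0.2, 0.4)

# top-comfort single-trial index bands per posture (generator calibration)
TOP_COMFORT_BANDS = {
    "supine": {"Pv": (1.72, 2.27), "Pm": (7.52, 9.21), "Gm": (1.95, 3.01), "Gv": (0.22, 0.38)},
    "lateral": {"Pv": (1.62, 1.95), "Pm": (7.36, 8.65), "Gm": (1.93, 2.36), "Gv": (0.23, 0.27)},
}

# key ergonomic node per partition
PARTITION_NODES = {
    "A1": "fourth cervical vertebra",
    "A2": "occipital eminence",
    "A3": "parietal foramen",
    "B1": "intersection of larynx and neck edge",
    "B2": "angle of mandible",
    "B3": "zygomatic arch",
    "B4": "parietal tuber",
}

# anthropometric groups: mean stature (cm) and mean weight (kg)
SUBJECT_GROUPS = {
    "MS": {"gender": "male", "height_cm": 168.4, "weight_kg": 57.3},
    "ML": {"gender": "male", "height_cm": 182.1, "weight_kg": 72.3},
    "FS": {"gender": "female", "height_cm": 153.5, "weight_kg": 48.4},
    "FL": {"gender": "female", "height_cm": 173.1, "weight_kg": 64.7},
}

# small-male prototype verification: (k calculated, k actually measured,
# relative error as printed in the verification report)
STIFFNESS_VERIFICATION_MS = {
    "A1": (0.13, 0.14, 0.07),
    "A2": (0.11, 0.10, 0.09),
    "A3": (0.15, 0.16, 0.07),
    "B1": (0.33, 0.34, 0.03),
    "B2": (0.26, 0.24, 0.11),
    "B3": (0.12, 0.11, 0.08),
    "B4": (0.14, 0.15, 0.07),
}
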