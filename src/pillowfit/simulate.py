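"""Seeded generators emulating a head/neck body-pressure study.

Every stage of the pipeline is testable offline through four generators:

* pressure matrices: smooth multi-lobe supine/lateral contact fields on a
  32x32 sensor grid (1.1 cm pitch), built as plateau-shaped anatomical
  cores (neck, occipital, jaw, temporal, ...) superposed on a connected
  low-pressure contact "sea", plus spatially correlated noise, thresholded
  to a contact footprint.  Amplitudes are calibrated so the index
  magnitudes (Pv ~ 1.6-2.3 kPa, Pm ~ 7.3-9.2 kPa, pointwise Gv ~ 0.2-0.4
  kPa/cm^2) match published top-comfort recordings;
* trial cohorts: a pillows x subjects design (default 7 x 6 = 42) where
  each pillow perturbs the template and the four comfort sub-scores are
  drawn from an ordered response whose mean falls with cosine distance to
  the template, with |Gv - 0.3| and with peak-pressure excess — so the
  top-decile trials are the ones nearest the template;
* expert judgment panels: nine-level pairwise scores derived from true
  sensitivities through the additively consistent complementary matrix
  (``a_ij = 10 (0.5 + (n-1)(w_i - w_j))``), plus optional noise, so the
  FAHP estimator recovers the generating weights;
* contour nodes and stiffness calibrations for the four anthropometric
  groups.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.special import expit

from . import reference
from .core import (
    ComfortScore,
    Posture,
    PressureMatrix,
    TrialRecord,
    mean_gradient,
    peak_pressure,
)
from .design import ContourNodes, ElasticCalibration
from .fahp import JudgmentMatrix, NINE_LEVEL
from .ideal import align_to_center, cosine_similarity

__all__ = [
    "Bump",
    "GeneratorConfig",
    "template_matrix",
    "generate_pressure_matrix",
    "generate_trial_cohort",
    "generate_expert_panel",
    "generate_contour_nodes",
    "generate_calibration",
]


@dataclass(frozen=True)
class Bump:
    """One anisotropic plateau lobe, optionally with a Gaussian peak on top.

    The plateau profile is ``amp * sigmoid(steep * (1 - r))`` with
    ``r = sqrt(((row-r0)/ry)^2 + ((col-c0)/rx)^2)``: flat near the center,
    dropping smoothly around the elliptical boundary (ry, rx in cells).
    """

    row: float
    col: float
    ry: float
    rx: float
    amp: float
    steep: float = 6.0
    peak_amp: float = 0.0
    peak_sigma: float = 1.5

    def render(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        r = np.hypot((rows - self.row) / self.ry, (cols - self.col) / self.rx)
        out = self.amp * expit(self.steep * (1.0 - r))
        if self.peak_amp > 0:
            d2 = (rows - self.row) ** 2 + (cols - self.col) ** 2
            out = out + self.peak_amp * np.exp(-0.5 * d2 / self.peak_sigma**2)
        return out


# Supine anatomy: a connected contact sea (whole head/neck footprint) with a
# posterior-neck core and a dominant occipital core; the parietal support is
# the remaining sea.  Lateral: cervical, jaw and temporal cores in the sea,
# the temporal one carrying the global peak; the lateral-parietal support is
# the remaining sea.
SUPINE_TEMPLATE: Tuple[Bump, ...] = (
    Bump(row=16.5, col=16.0, ry=11.5, rx=9.5, amp=0.85, steep=6.0),  # contact sea
    Bump(row=6.5, col=16.0, ry=3.1, rx=6.0, amp=1.3, steep=300.0),  # posterior neck
    Bump(row=14.0, col=16.0, ry=4.7, rx=7.0, amp=2.1, steep=300.0, peak_amp=5.2, peak_sigma=0.7),  # occipital
)

LATERAL_TEMPLATE: Tuple[Bump, ...] = (
    Bump(row=16.5, col=16.0, ry=11.5, rx=10.0, amp=0.85, steep=6.0),  # contact sea
    Bump(row=6.0, col=16.0, ry=2.9, rx=5.5, amp=1.3, steep=300.0),  # cervical
    Bump(row=16.0, col=9.5, ry=3.4, rx=2.7, amp=0.9, steep=300.0),  # jaw
    Bump(row=16.0, col=20.0, ry=4.4, rx=4.4, amp=2.1, steep=300.0, peak_amp=5.2, peak_sigma=0.7),  # temporal
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate the reference study's conditions: a desk-scale 32x32
    grid standing in for the 1200-point mat, 7 pillows x 6 subjects per
    posture, and comfort-response coefficients that make subjective totals
    fall with distance from the ideal template.
    """

    shape: Tuple[int, int] = (32, 32)
    pitch_cm: float = 1.1
    contact_threshold_kpa: float = 0.3
    noise_sd_kpa: float = 0.08
    noise_smooth_cells: float = 1.2
    n_pillows: int = 7
    n_subjects: int = 6
    pillow_perturbation_step: float = 0.055
    # comfort response: mean sub-score = 1 + 4 * closeness - penalties
    similarity_floor: float = 0.86
    gv_penalty: float = 2.0
    gv_target: float = 0.3
    pm_penalty: float = 0.5
    pm_ceiling_kpa: float = 9.2
    comfort_noise_sd: float = 0.35
    seed: int = 0

    def template(self, posture: Posture | str) -> Tuple[Bump, ...]:
        return SUPINE_TEMPLATE if Posture.coerce(posture) == Posture.SUPINE else LATERAL_TEMPLATE


def _render_field(bumps: Sequence[Bump], shape: Tuple[int, int]) -> np.ndarray:
    rows, cols = np.indices(shape, dtype=float)
    field_ = np.zeros(shape)
    for b in bumps:
        field_ += b.render(rows, cols)
    return field_


def _correlated_noise(
    shape: Tuple[int, int], sd: float, smooth: float, rng: np.random.Generator
) -> np.ndarray:
    if sd <= 0:
        return np.zeros(shape)
    white = rng.normal(0.0, 1.0, size=shape)
    sm = ndimage.gaussian_filter(white, smooth)
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def template_matrix(posture: Posture | str, config: GeneratorConfig = GeneratorConfig()) -> PressureMatrix:
    """The noiseless posture template (the generating 'ideal' field)."""
    field_ = _render_field(config.template(posture), config.shape)
    field_[field_ < config.contact_threshold_kpa] = 0.0
    return PressureMatrix(field_, config.pitch_cm, config.contact_threshold_kpa)


def generate_pressure_matrix(
    posture: Posture | str,
    config: GeneratorConfig = GeneratorConfig(),
    seed: Optional[int] = None,
    bumps: Optional[Sequence[Bump]] = None,
) -> PressureMatrix:
    """One noisy pressure recording: template + correlated noise, thresholded.

    With ``noise_sd_kpa == 0`` this is exactly the template, independent of
    the seed; otherwise the same seed reproduces the same matrix bit for bit.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    field_ = _render_field(bumps if bumps is not None else config.template(posture), config.shape)
    field_ = field_ + _correlated_noise(config.shape, config.noise_sd_kpa, config.noise_smooth_cells, rng)
    np.clip(field_, 0.0, None, out=field_)
    field_[field_ < config.contact_threshold_kpa] = 0.0
    return PressureMatrix(field_, config.pitch_cm, config.contact_threshold_kpa)


def _perturbed_bumps(
    bumps: Sequence[Bump], rho: float, rng: np.random.Generator
) -> List[Bump]:
    """Pillow-specific template distortion of magnitude rho (0 = none)."""
    if rho == 0:
        return list(bumps)
    dr, dc = rng.normal(0.0, 2.5 * rho, size=2)
    out = []
    for b in bumps:
        amp = b.amp * float(np.clip(1.0 + rng.normal(0.0, 1.2 * rho), 0.55, 1.6))
        peak = b.peak_amp * float(np.clip(1.0 + rng.normal(0.0, 1.5 * rho), 0.4, 1.8))
        width = float(np.clip(1.0 + rng.normal(0.0, 0.8 * rho), 0.6, 1.5))
        out.append(
            replace(
                b,
                row=b.row + dr,
                col=b.col + dc,
                ry=b.ry * width,
                rx=b.rx * width,
                amp=amp,
                peak_amp=peak,
            )
        )
    return out


def generate_trial_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    posture: Posture | str = Posture.SUPINE,
    seed: Optional[int] = None,
    n_trials: Optional[int] = None,
) -> List[TrialRecord]:
    """A pillows x subjects cohort with comfort responses.

    Pillow ``P1`` reproduces the template exactly up to measurement noise;
    pillow ``Pk`` distorts it with magnitude ``(k-1) * pillow_perturbation_step``.
    Comfort sub-scores are ordered-categorical draws whose mean increases
    with the cosine closeness of the center-of-pressure-aligned recording
    to the aligned template and decreases with |Gv - target| and with peak
    pressures beyond the ceiling. ``n_trials`` optionally
    truncates the pillow-major enumeration.
    """
    posture = Posture.coerce(posture)
    root = np.random.default_rng(config.seed if seed is None else seed)
    template = template_matrix(posture, config)
    template_aligned = align_to_center(template)[0]
    trials: List[TrialRecord] = []
    total = config.n_pillows * config.n_subjects if n_trials is None else n_trials
    made = 0
    for p in range(config.n_pillows):
        rho = p * config.pillow_perturbation_step
        pillow_rng = np.random.default_rng(root.integers(2**31))
        bumps = _perturbed_bumps(config.template(posture), rho, pillow_rng)
        for s in range(config.n_subjects):
            if made >= total:
                break
            trial_seed = int(root.integers(2**31))
            m = generate_pressure_matrix(posture, config, seed=trial_seed, bumps=bumps)
            sim = cosine_similarity(align_to_center(m)[0], template_aligned)
            gv = mean_gradient(m, mode="pointwise")
            pm = peak_pressure(m)
            closeness = np.clip(
                (sim - config.similarity_floor) / (1.0 - config.similarity_floor), 0.0, 1.0
            )
            mu = (
                1.0
                + 4.0 * closeness
                - config.gv_penalty * abs(gv - config.gv_target)
                - config.pm_penalty * max(0.0, pm - config.pm_ceiling_kpa)
            )
            score_rng = np.random.default_rng(trial_seed + 1)
            subs = np.clip(
                np.rint(mu + score_rng.normal(0.0, config.comfort_noise_sd, size=4)), 1, 5
            ).astype(int)
            trials.append(
                TrialRecord(
                    pillow_id=f"P{p + 1}",
                    subject_id=f"S{s + 1}",
                    posture=posture,
                    matrix=m,
                    comfort=ComfortScore(*[int(x) for x in subs]),
                    emg_valid=True,
                )
            )
            made += 1
    return trials


def generate_expert_panel(
    n_experts: int = 10,
    true_sensitivities: Optional[Mapping[str, float]] = None,
    noise_sd: float = 0.5,
    seed: Optional[int] = None,
    discretize: bool = True,
) -> List[JudgmentMatrix]:
    """Nine-level pairwise judgment matrices from true sensitivities.

    The ideal pair score is ``a_ij = 10 (0.5 + (n-1)(w_i - w_j))`` with w
    the normalized sensitivities — the additively consistent complementary
    matrix on the ten-point scale — so converting and weighting recovers w
    (exactly at zero noise when no score clips).  Expert noise perturbs each
    pair score once (keeping ``a_ij + a_ji = 10`` up to clipping);
    ``discretize`` rounds scores to whole scale levels.
    """
    if true_sensitivities is None:
        true_sensitivities = reference.PARTITION_SENSITIVITY_WEIGHTS
    labels = tuple(true_sensitivities)
    s = np.array([true_sensitivities[l] for l in labels], dtype=float)
    if np.any(s <= 0):
        raise ValueError("sensitivities must be positive")
    w = s / s.sum()
    n = len(labels)
    ideal = 10.0 * (0.5 + (n - 1.0) * (w[:, None] - w[None, :]))
    rng = np.random.default_rng(seed)
    panel: List[JudgmentMatrix] = []
    for e in range(n_experts):
        a = np.full((n, n), 5.0)
        for i in range(n):
            for j in range(i + 1, n):
                score = ideal[i, j] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                if discretize:
                    score = float(np.rint(score))
                a[i, j] = min(9.0, max(1.0, score))
                a[j, i] = min(9.0, max(1.0, 10.0 - score))
        panel.append(JudgmentMatrix(a, labels, NINE_LEVEL, expert_id=f"E{e + 1}"))
    return panel


# nominal contour-node geometry for the small-male group: per partition,
# (x position along the contour in mm, compression depth in mm)
_BASE_NODES: Dict[str, Tuple[float, float]] = {
    "A1": (60.0, 45.0),
    "A2": (150.0, 62.0),
    "A3": (250.0, 40.0),
    "B1": (55.0, 50.0),
    "B2": (140.0, 35.0),
    "B3": (165.0, 70.0),
    "B4": (260.0, 40.0),
}


def generate_contour_nodes(
    group: str,
    seed: Optional[int] = None,
    jitter_sd_mm: float = 1.5,
    partitions: Optional[Sequence[str]] = None,
) -> ContourNodes:
    """Contour nodes for one anthropometric group (MS, ML, FS, FL).

    Node depths scale with the group's mean stature relative to the
    small-male group, so a larger physique sinks deeper at every node; the
    seeded jitter is applied to the base depths before scaling, keeping the
    between-group ordering monotone.
    """
    if group not in reference.SUBJECT_GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(reference.SUBJECT_GROUPS)}")
    scale = reference.SUBJECT_GROUPS[group]["height_cm"] / reference.SUBJECT_GROUPS["MS"]["height_cm"]
    rng = np.random.default_rng(seed)
    names = partitions if partitions is not None else list(_BASE_NODES)
    nodes: Dict[str, Tuple[str, float, float]] = {}
    for part in names:
        x, depth = _BASE_NODES[part]
        jitter = rng.normal(0.0, jitter_sd_mm) if jitter_sd_mm > 0 else 0.0
        d = float(np.clip((depth + jitter) * scale, 5.0, reference.FOAM_HEIGHT_MM - 5.0))
        nodes[part] = (reference.PARTITION_NODES.get(part, part), x, d)
    return ContourNodes(group=group, nodes=nodes)


def generate_calibration(
    a: float = reference.POWER_LAW_A,
    b: float = reference.POWER_LAW_B,
    d_grid: Sequence[float] = tuple(p[0] for p in reference.ELASTIC_CALIBRATION_PAIRS),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> ElasticCalibration:
    """Calibration pairs from ``k = (d / a)^(1/b)``, optionally noisy.

    Multiplicative log-normal noise on k; monotonicity (stiffness strictly
    decreasing with diameter) is enforced after noising so the result is
    always a valid calibration.
    """
    rng = np.random.default_rng(seed)
    k = (np.asarray(d_grid, dtype=float) / a) ** (1.0 / b)
    if noise_sd > 0:
        k = k * np.exp(rng.normal(0.0, noise_sd, size=k.shape))
        for i in range(1, k.size):  # restore strict decrease where noise broke it
            k[i] = min(k[i], 0.99 * k[i - 1])
    return ElasticCalibration.fit(list(zip(d_grid, k)))
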