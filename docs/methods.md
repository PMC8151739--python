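# Methods

This note documents the model, the numerical choices, the synthetic-data
generator, and the limitations of `pillowfit`.

## Pressure indices and gradient conventions

A recording is a non-negative matrix of contact pressures (kPa) on a
regular sensor grid with pitch `l` (cm). Row 0 is the neck edge; rows grow
toward the crown. Four indices summarize a matrix or a region of it:
average pressure `Pv`, peak pressure `Pm`, maximum gradient `Gm` and mean
gradient `Gv`.

Two gradient conventions coexist in the pressure-mat literature and both
are implemented:

* **literal (row-sum)**: `G_i = Σ_j [p(x_i, y_j) − p(x_{i−1}, y_j)] / l`,
  one signed value per row pair. `Gm`/`Gv` aggregate `|G_i|` so that
  `0 ≤ Gv ≤ Gm` also holds for fields that decrease toward the crown.
  Because the column sum accumulates ~20–30 cells, this quantity is an
  order of magnitude larger than any per-cell slope.
* **pointwise**: per-cell central-difference magnitude `√(gx² + gy²)`
  sampled at pitch `l`, aggregated over contact cells.

The index functions default to the literal form; the *pipeline* defaults
to the pointwise form, because the comfortable-support band
`Gv ∈ [0.2, 0.4]` kPa/cm² only describes per-cell slopes. The unit label
kPa/cm² is carried for both modes as is conventional, although the literal
row-sum strictly has units of kPa/cm accumulated over a row.

Averages are computed over contact cells by default (threshold 0.1 kPa for
raw data types; the generator uses 0.3 kPa) so that off-body sensor cells
do not dilute `Pv`; a global mode retains the plain arithmetic mean.

## Ideal matrix construction

Trials of one posture are ranked by comfort total (ties: higher minimum
sub-score, then lexicographic trial id). The top fraction (default 0.10)
is kept; rounding is configurable (`floor` default — a 42-trial cohort
keeps 4 — with `ceil` available) and never drops below `min_keep = 1`.

Kept matrices are aligned before averaging: each is shifted by whole cells
so its center of pressure lands on the **integer center cell**
`(rows//2, cols//2)`. A half-integer target (the geometric center of an
even grid) would put every center-of-pressure estimate exactly on a
rounding boundary, so that measurement noise flips shifts by one cell and
the average blurs anatomically corresponding peaks — the integer target
makes alignment reproducible. Alignment can be disabled.

Similarity between matrices is the cosine of the flattened vectors; it is
1 exactly for positive scalar multiples and lies in [0, 1] for
non-negative fields. Evaluation canonicalizes candidate trials into the
same aligned frame before comparing; mixing an aligned ideal with raw
trials systematically understates similarity.

## Fuzzy c-means partitioning

FCM clusters the scalar pressure values of the contact cells (c = 3,
m = 2), so spatial structure enters only through post-processing — this is
how three pressure levels can produce four lateral regions when two
anatomically distinct areas share a level. Numerical choices:

* centers initialized at evenly spaced percentiles (25/50/75 for c = 3)
  of the contact pressures plus seeded jitter (0.5% of the data range);
  deterministic given (values, c, m, seed);
* alternating optimization; exact-zero distances get crisp membership;
  convergence when the largest center shift drops below 1e-6 (300
  iteration cap; non-convergence is flagged on the result, not raised);
* the objective trace is recorded per iteration and is non-increasing (a
  property test asserts this over 100 seeded runs);
* cluster labels are sorted by ascending center so relabeling cannot
  change downstream results.

Each cluster is split into 4-connected components (4- not 8-connectivity,
so diagonal touching does not bridge distinct regions). Components smaller
than 1% of the contact cells are merged into the neighbouring region with
the longest shared boundary (ties: lower label; isolated islands fall back
to background). Final regions are relabeled 1..K by centroid.

Naming: supine regions are ordered by centroid row from the neck edge
(A1, A2, A3). Lateral: B1 is the neck-edge region, B3 the
highest-mean-pressure region among the rest (the temporal bone carries the
peak), B2 the more anterior (smaller centroid column) of the remaining
two, B4 the last. Strict mode requires 3/4 regions; otherwise extra
regions get deterministic suffixes (B4a, B4b, ...).

## FAHP sensitivity weights

Nine-level pair strengths `a_ij` convert to a complementary matrix via
`V_ij = a_ij / (a_ij + a_ji)` — order-preserving, indifference ↦ 0.5,
reciprocal-consistent. The row-sum rule
`W_i = (Σ_j V_ij + n/2 − 1)/(n(n−1))` yields weights that sum to 1 for any
complementary matrix (algebraic identity; property-tested).

For these weights, an additively consistent matrix satisfies
`V_ij = 0.5 + (n−1)(W_i − W_j)` — this follows directly from the row-sum
formula and is verified numerically (building a matrix from a weight
vector by this relation and re-deriving weights returns the vector
exactly). The compatibility index is the mean absolute deviation from
that reconstruction over the strict upper triangle,
`CI = 2/(n(n−1)) Σ_{i<j} |V_ij − V̂_ij|`, reported with every weight
vector; CI ≤ 0.1 counts as consistent. Note the reconstruction can leave
[0, 1] when the weight spread exceeds `0.5/(n−1)`; for the 3–4 item
posture groups used here it stays in range.

The hierarchy has a posture layer (supine/lateral) over partition layers;
final weights are products `WB_g · WC_{g,i}` and remain normalized. A
panel is aggregated by averaging per-expert weight vectors (renormalized),
matching the convention of reporting a final weight average.

Overall comfort is `Σ x_i w_i` over per-partition ratings — a convex
combination, so it stays within the rating range. When per-partition
ratings are absent the weighted score is omitted, never imputed.

## Material design

Units are fixed as kPa · cm² → N via 1 kPa·cm² = 0.1 N; stiffness k is
N/mm. Per partition, `ΔF` integrates the ideal matrix over the partition's
cells, `ΔH` is the compression depth of the group's contour node, and
`k = ΔF/ΔH`. The pore-diameter law `d = a k^b` is fitted by ordinary least
squares in log-log space; on the packaged six-point calibration this gives
a = 3.613, b = −0.769 (R² ≈ 0.98). Predictions are clamped to the
calibration's 6–21 mm validity range (clamping is flagged in layouts)
rather than extrapolated. Hole layouts use a hexagonal staggered lattice
at 30 mm pitch (nearest-neighbour distance exactly the pitch); a diameter
at or above the pitch would overlap and raises an error.

## Synthetic-data generator

The generator emulates the study design: 7 pillows × 6 subjects per
posture on a 32×32 grid at 1.1 cm pitch (a desk-scale stand-in for a
1200-point mat), with per-trial spatially correlated measurement noise
(SD 0.08 kPa, 1.2-cell correlation) and a contact threshold of 0.3 kPa.

Templates are sums of plateau lobes on a gentle connected contact "sea":
supine has posterior-neck and occipital cores (the occipital one carries a
narrow Gaussian peak reaching ≈ 8.1 kPa); lateral has cervical, jaw and
temporal cores with the peak on the temporal bone. Amplitudes and extents
were calibrated once so the template indices sit in the magnitude bands of
published top-comfort recordings (Pv ≈ 1.2–1.6 kPa, Pm ≈ 7.4–8.7 kPa,
pointwise Gv ≈ 0.3–0.36) and so the partition structure is stable: the
core shoulders are made nearly hard (logistic steepness 300), because soft
shoulders create rings of intermediate pressure that fuzzy clustering
turns into spurious regions. With cores as value-separated islands in a
single-level sea, the region count is structurally `#cores + 1` however
FCM distributes the cores among clusters — measured stability is ≥ 98/100
seeds per posture on pipeline ideal matrices.

Pillow k distorts the template with magnitude `(k−1)·0.055` (amplitude,
width and position perturbations); pillow 1 is undistorted. Comfort
sub-scores are ordered-categorical draws: each has mean
`1 + 4·closeness − 2·|Gv − 0.3| − 0.5·max(0, Pm − 9.2)` with closeness the
aligned-frame cosine similarity to the template rescaled from
[0.86, 1] → [0, 1], plus N(0, 0.35) noise, clipped to 1–5. This makes the
top-decile trials the ones nearest the template (required for template
recovery) and gives a strong similarity–comfort rank correlation
(ρ ≥ 0.87 across seeds).

Expert panels are generated through the additively consistent matrix of
the true (normalized) sensitivities, `a_ij = 10(0.5 + (n−1)(w_i − w_j))`,
plus per-pair noise, optionally rounded to whole scale levels; the FAHP
estimator therefore recovers the generating weights (exactly at zero
noise without rounding; MAE ≈ 0.004 at noise SD 0.5 with 10 experts).
Contour-node depths scale with group stature (shared per-node jitter keeps
the larger-physique-sinks-deeper ordering exact); calibrations invert the
power law with optional log-normal noise, re-monotonized.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real pressure fields are smoother than the
hard-shouldered plateaus used here and their comfort responses are noisier
and subject-specific; partition counts on real recordings are not
guaranteed to be 3/4; the total contact force (~50–90 N here) and the
resulting per-partition stiffness requirements are only
order-of-magnitude realistic, so some partitions clamp to the 6 mm pore
bound; EMG validity is always true; and published per-partition index
tables and prototype verification rows derive from unreleased
human-subject recordings and are packaged as reference data, not
reproduced.

## Problem sizes

Defaults were chosen to keep every run desk-scale: 42-trial cohorts on
32×32 grids, 100-seed stability scans, 1000-matrix weight-normalization
sweeps, 200-point grid-search oracles for the FCM check. The full test
suite runs in well under a minute; the acceptance script in ~10 s.

## Known limitations

* The literal gradient mode follows the printed row-sum formula and is
  retained for fidelity, but no claim is made that published gradient
  values were computed this way (they are consistent with the pointwise
  convention); neither mode is calibrated against raw mat data.
* How three pressure clusters map to four lateral partitions is a
  reconstruction (value clustering + connected components); the original
  procedure is not fully specified.
* The consistency test for judgment matrices is the standard
  compatibility index; other conventions exist.
* The mapping of partition geometry onto pillow-surface millimetres is a
  plain pitch-scaled projection; no contour warping is attempted.
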