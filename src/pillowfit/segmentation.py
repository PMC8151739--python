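"""Fuzzy c-means segmentation of the ideal matrix into support partitions.

The pressure values of an ideal matrix vary smoothly, with no visible
region boundaries.  Clustering the scalar *pressure values* of the contact
cells with fuzzy c-means (FCM, fuzzifier m, c clusters; here c=3, m=2)
exposes the latent support levels; splitting each pressure-level cluster
into 4-connected spatial components then yields the named support
partitions.  This is how c=3 pressure levels can produce four lateral
regions: two spatially disjoint areas may share a pressure level.

FCM minimizes ``J_m = sum_i sum_k u_ik^m (x_i - v_k)^2`` by alternating
membership and center updates; the objective is non-increasing at every
iteration and the run is deterministic given (values, c, m, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import NoContactError, Posture, PressureMatrix

__all__ = ["FCMResult", "PartitionMap", "fcm", "label_map", "name_partitions"]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class FCMResult:
    """Converged state of a fuzzy c-means run on 1-D pressure values."""

    memberships: np.ndarray  # (n, c), rows sum to 1
    centers: np.ndarray  # (c,), sorted ascending
    objective_trace: Tuple[float, ...]
    c: int
    m_fuzz: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class PartitionMap:
    """Integer region labels on the sensor grid.

    Label 0 is background (no contact); labels 1..K are regions.  ``names``
    maps every region label to an anatomical name once
    :func:`name_partitions` has run (before that, to a placeholder).
    """

    labels: np.ndarray
    names: Dict[int, str]
    posture: Optional[Posture] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=int).copy()
        arr.setflags(write=False)
        object.__setattr__(self, "labels", arr)
        present = set(np.unique(arr)) - {0}
        if not present:
            raise ValueError("partition map has no labeled regions")
        if present != set(self.names):
            raise ValueError(
                f"names {sorted(self.names)} do not cover region labels {sorted(present)}"
            )

    @property
    def region_labels(self) -> List[int]:
        return sorted(self.names)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def renamed(self, names: Dict[int, str], posture: Optional[Posture] = None) -> "PartitionMap":
        return PartitionMap(self.labels, names, posture or self.posture)


def _memberships(x: np.ndarray, centers: np.ndarray, m_fuzz: float) -> np.ndarray:
    d2 = (x[:, None] - centers[None, :]) ** 2
    # exact hits get crisp membership on their (nearest) center
    hit = d2 < 1e-300
    u = np.zeros_like(d2)
    any_hit = hit.any(axis=1)
    if any_hit.any():
        first = hit[any_hit].argmax(axis=1)
        u[np.flatnonzero(any_hit), first] = 1.0
    rest = ~any_hit
    if rest.any():
        p = d2[rest] ** (-1.0 / (m_fuzz - 1.0))
        u[rest] = p / p.sum(axis=1, keepdims=True)
    return u


def fcm(
    values: Sequence[float] | np.ndarray,
    c: int = 3,
    m_fuzz: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: Optional[int] = None,
) -> FCMResult:
    """Fuzzy c-means on a 1-D feature (pressure value).

    Centers are initialized at evenly spaced percentiles of the data (25/50/75
    for c=3) plus a small seeded jitter, then alternately updated with the
    memberships until the largest center shift falls below ``tol``.
    Non-convergence within ``max_iter`` is flagged on the result, not raised.
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.unique(x).size < c:
        raise ValueError(f"need at least c={c} distinct values, got {np.unique(x).size}")
    if m_fuzz <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    qs = 100.0 * (np.arange(1, c + 1)) / (c + 1)
    centers = np.percentile(x, qs)
    span = float(x.max() - x.min())
    centers = centers + rng.normal(0.0, 0.005 * span, size=c)

    trace: List[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = _memberships(x, centers, m_fuzz)
        um = u ** m_fuzz
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        trace.append(float((um * (x[:, None] - new_centers[None, :]) ** 2).sum()))
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            converged = True
            break
    u = _memberships(x, centers, m_fuzz)
    order = np.argsort(centers)
    return FCMResult(
        memberships=u[:, order],
        centers=centers[order],
        objective_trace=tuple(trace),
        c=c,
        m_fuzz=m_fuzz,
        converged=converged,
        n_iter=it,
    )


def _boundary_lengths(labels: np.ndarray, mask: np.ndarray) -> Dict[int, int]:
    """Shared 4-neighbour boundary length between ``mask`` and every other
    positive region in ``labels``."""
    counts: Dict[int, int] = {}
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.roll(labels, (dr, dc), axis=(0, 1))
        # roll wraps around; mask out wrapped rows/cols
        valid = np.ones_like(mask)
        if dr == 1:
            valid[0, :] = False
        elif dr == -1:
            valid[-1, :] = False
        if dc == 1:
            valid[:, 0] = False
        elif dc == -1:
            valid[:, -1] = False
        neigh = shifted[mask & valid]
        for lab in np.unique(neigh):
            if lab > 0:
                counts[int(lab)] = counts.get(int(lab), 0) + int((neigh == lab).sum())
    return counts


def label_map(
    f: FCMResult,
    m: PressureMatrix,
    min_region_cells: Optional[int] = None,
) -> PartitionMap:
    """Turn FCM memberships into a spatial partition map.

    Each contact cell takes its argmax-membership cluster; every cluster is
    split into 4-connected components; components smaller than
    ``min_region_cells`` (default 1% of the contact cells, at least 1) are
    merged into the neighbouring region sharing the longest boundary (tie:
    lower label; no positive neighbour: background).  Final regions are
    relabeled 1..K ordered by centroid row then column.
    """
    mask = m.contact_mask
    n_contact = int(mask.sum())
    if n_contact == 0:
        raise NoContactError("all cells are background; nothing to partition")
    if f.memberships.shape[0] != n_contact:
        raise ValueError(
            f"FCM result has {f.memberships.shape[0]} samples but the matrix "
            f"has {n_contact} contact cells"
        )
    if min_region_cells is None:
        min_region_cells = max(1, int(round(0.01 * n_contact)))

    assign = f.memberships.argmax(axis=1)  # cluster per contact cell
    cluster_grid = np.full(m.shape, -1, dtype=int)
    cluster_grid[mask] = assign

    labels = np.zeros(m.shape, dtype=int)
    next_label = 1
    for k in range(f.c):
        comp, n_comp = ndimage.label(cluster_grid == k, structure=_FOUR_CONN)
        for j in range(1, n_comp + 1):
            labels[comp == j] = next_label
            next_label += 1

    # merge undersized regions into the neighbour with the longest shared boundary
    while True:
        sizes = {int(l): int((labels == l).sum()) for l in np.unique(labels) if l > 0}
        if len(sizes) <= 1:
            break
        small = [l for l, s in sorted(sizes.items(), key=lambda kv: (kv[1], kv[0])) if s < min_region_cells]
        if not small:
            break
        lab = small[0]
        region = labels == lab
        shared = _boundary_lengths(labels, region)
        shared.pop(lab, None)
        if shared:
            best = max(shared.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            labels[region] = best
        else:
            labels[region] = 0  # isolated island: drop to background
            if len(sizes) - 1 <= 1:
                break

    # deterministic relabel by centroid (row, then col)
    finals = [int(l) for l in np.unique(labels) if l > 0]
    if not finals:
        raise NoContactError("all regions merged into background")
    centroids = {l: ndimage.center_of_mass(labels == l) for l in finals}
    ordered = sorted(finals, key=lambda l: (centroids[l][0], centroids[l][1]))
    out = np.zeros_like(labels)
    for new, old in enumerate(ordered, start=1):
        out[labels == old] = new
    names = {i: f"R{i}" for i in range(1, len(ordered) + 1)}
    return PartitionMap(out, names)


_SUPINE_NAMES = ("A1", "A2", "A3")  # posterior neck, occipital, posterior parietal
_LATERAL_NAMES = ("B1", "B2", "B3", "B4")  # cervical, jaw, temporal, lateral parietal


def name_partitions(
    pm: PartitionMap,
    posture: Posture | str,
    matrix: Optional[PressureMatrix] = None,
    strict: bool = True,
) -> PartitionMap:
    """Assign anatomical names to regions.

    Supine (3 regions expected): ordered by centroid row from the neck edge
    -> A1 (posterior neck), A2 (occipital), A3 (posterior parietal).

    Lateral (4 regions expected): B1 = neck-edge region (smallest centroid
    row); B3 = highest-mean-pressure remaining region (temporal bone,
    requires ``matrix``); of the last two, B2 = anterior/jaw-side region
    (smaller centroid column) and B4 = parietal-edge region.

    In strict mode an unexpected region count raises; otherwise the largest
    regions get the canonical names and extras are suffixed a, b, ...
    deterministically.
    """
    posture = Posture.coerce(posture)
    canon = _SUPINE_NAMES if posture == Posture.SUPINE else _LATERAL_NAMES
    region = pm.region_labels
    if strict and len(region) != len(canon):
        raise ValueError(
            f"expected {len(canon)} regions for {posture.value} posture, got {len(region)}"
        )

    centroids = {l: ndimage.center_of_mass(pm.labels == l) for l in region}
    # main regions: the largest len(canon) by cell count (all of them in strict mode)
    sizes = {l: int((pm.labels == l).sum()) for l in region}
    main = sorted(sorted(region), key=lambda l: -sizes[l])[: len(canon)]
    extras = [l for l in sorted(region) if l not in main]

    names: Dict[int, str] = {}
    if posture == Posture.SUPINE:
        for name, l in zip(canon, sorted(main, key=lambda l: centroids[l][0])):
            names[l] = name
    else:
        pool = sorted(main, key=lambda l: centroids[l][0])
        b1 = pool.pop(0)
        names[b1] = "B1"
        if len(pool) >= 1:
            if matrix is not None:
                means = {l: float(matrix.values[pm.labels == l].mean()) for l in pool}
                b3 = max(pool, key=lambda l: (means[l], -l))
            else:
                b3 = max(pool, key=lambda l: -centroids[l][0])  # fallback: central-most
            pool.remove(b3)
            names[b3] = "B3"
        if len(pool) == 2:
            b2 = min(pool, key=lambda l: (centroids[l][1], l))
            pool.remove(b2)
            names[b2] = "B2"
        elif len(pool) == 1:
            names[pool.pop(0)] = "B2"
        if pool:
            names[pool.pop(0)] = "B4"
    # any canonical name not yet used goes to remaining mains in label order
    used = set(names.values())
    leftover_names = [n for n in canon if n not in used]
    leftover_labels = [l for l in main if l not in names]
    for n, l in zip(leftover_names, leftover_labels):
        names[l] = n
    # extras: suffix the last canonical name deterministically
    for i, l in enumerate(extras):
        names[l] = f"{canon[-1]}{chr(ord('a') + i)}"
    return pm.renamed(names, posture)
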