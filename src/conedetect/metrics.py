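"""Matching of automatic to manual cones and performance/agreement metrics.

An automatic cone is a true positive when it lies within a distance ``d`` of
a manual cone, with ``d = 0.75 x`` the median nearest-neighbor spacing of the
manual cones in that image; when several automatic cones fall within ``d`` of
one manual cone only the closest counts, the rest are false positives. Both
point sets are pruned of cones within 7 px of the image edges before
matching. The counts then satisfy

    N_automatic = N_TP + N_FP        N_manual = N_TP + N_FN

and performance per image is summarized by

    true positive rate   = N_TP / N_manual
    false discovery rate = N_FP / N_automatic
    Dice's coefficient   = 2 N_TP / (N_manual + N_automatic)

Cone density (cones per mm^2) and Bland-Altman limits of agreement complete
the comparison with manual grading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import ConeImage, MarkedCones

__all__ = [
    "MatchResult",
    "MetricsRecord",
    "BlandAltman",
    "DEFAULT_BORDER_PX",
    "match_radius",
    "prune_border",
    "match_cones",
    "compute_metrics",
    "cone_density",
    "bland_altman",
]

DEFAULT_BORDER_PX = 7.0
MEDIAN_SPACING_FACTOR = 0.75


@dataclass
class MatchResult:
    """One-to-one correspondence between automatic and manual cones."""

    pairs: list[tuple[int, int, float]]  # (auto idx, manual idx, distance px)
    unmatched_auto: list[int]  # false positives
    unmatched_manual: list[int]  # false negatives
    d: float  # match radius, px

    @property
    def n_tp(self) -> int:
        return len(self.pairs)

    @property
    def n_fp(self) -> int:
        return len(self.unmatched_auto)

    @property
    def n_fn(self) -> int:
        return len(self.unmatched_manual)

    @property
    def n_automatic(self) -> int:
        return self.n_tp + self.n_fp

    @property
    def n_manual(self) -> int:
        return self.n_tp + self.n_fn


@dataclass
class MetricsRecord:
    """Per-image performance; a rate is None when its denominator is zero."""

    true_positive_rate: float | None
    false_discovery_rate: float | None
    dice: float | None


@dataclass
class BlandAltman:
    """Mean difference and 95% limits of agreement (mean +- 1.96 SD)."""

    mean_difference: float
    lower_limit: float
    upper_limit: float
    sd: float
    n: int


def match_radius(manual: MarkedCones, method: str = "nearest") -> float:
    """0.75 x the median inter-cone spacing of the manual cones.

    ``method="nearest"`` (default) takes each cone's nearest-neighbor
    distance; ``method="voronoi"`` takes each cone's mean distance to its
    Voronoi-adjacent neighbors — two common readings of mosaic "spacing",
    exposed because the original description does not define the term.
    """
    pts = np.asarray(manual.points, dtype=float)
    if len(pts) < 2:
        raise ValueError("match radius needs at least 2 manual cones")
    if method == "nearest":
        dists, _ = cKDTree(pts).query(pts, k=2)
        spacing = np.median(dists[:, 1])
    elif method == "voronoi":
        from scipy.spatial import Voronoi
        if len(pts) < 4:
            raise ValueError("Voronoi spacing needs at least 4 manual cones")
        vor = Voronoi(pts)
        neighbor_d: dict[int, list[float]] = {}
        for i, j in vor.ridge_points:
            dist = float(np.hypot(*(pts[i] - pts[j])))
            neighbor_d.setdefault(int(i), []).append(dist)
            neighbor_d.setdefault(int(j), []).append(dist)
        spacing = np.median([np.mean(v) for v in neighbor_d.values()])
    else:
        raise ValueError(f"unknown spacing method {method!r}")
    return MEDIAN_SPACING_FACTOR * float(spacing)


def prune_border(points: np.ndarray, image_dims: tuple[int, int],
                 border: float = DEFAULT_BORDER_PX) -> np.ndarray:
    """Indices of points at least ``border`` px away from every image edge."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    h, w = image_dims
    x, y = pts[:, 0], pts[:, 1]
    keep = (x >= border) & (x <= w - 1 - border) & (y >= border) & (y <= h - 1 - border)
    return np.flatnonzero(keep)


def match_cones(
    auto: MarkedCones,
    manual: MarkedCones,
    d: float,
    image_dims: tuple[int, int] | None = None,
    border: float = DEFAULT_BORDER_PX,
) -> MatchResult:
    """Greedy one-to-one matching of automatic to manual cones.

    Both sets are first pruned of points within ``border`` px of the image
    edges (skipped when ``image_dims`` is None). Candidate pairs closer than
    ``d`` are then accepted in ascending distance order, each point used at
    most once — which realizes the per-cone "closest automatic cone wins"
    rule. Exact distance ties break on the lower manual index, then the
    lower automatic index. Indices in the result refer to the original
    (unpruned) point lists.
    """
    if not d > 0:
        raise ValueError("match radius d must be > 0")
    a_pts = np.asarray(auto.points, dtype=float).reshape(-1, 2)
    m_pts = np.asarray(manual.points, dtype=float).reshape(-1, 2)
    if image_dims is not None:
        a_idx = prune_border(a_pts, image_dims, border)
        m_idx = prune_border(m_pts, image_dims, border)
    else:
        a_idx = np.arange(len(a_pts))
        m_idx = np.arange(len(m_pts))
    a_kept, m_kept = a_pts[a_idx], m_pts[m_idx]

    pairs: list[tuple[int, int, float]] = []
    if len(a_kept) and len(m_kept):
        tree = cKDTree(m_kept)
        cand: list[tuple[float, int, int]] = []  # (distance, manual local, auto local)
        for ai, neighbors in enumerate(tree.query_ball_point(a_kept, d)):
            for mi in neighbors:
                dist = float(np.hypot(*(a_kept[ai] - m_kept[mi])))
                cand.append((dist, mi, ai))
        cand.sort()
        a_used = np.zeros(len(a_kept), dtype=bool)
        m_used = np.zeros(len(m_kept), dtype=bool)
        for dist, mi, ai in cand:
            if a_used[ai] or m_used[mi]:
                continue
            a_used[ai] = m_used[mi] = True
            pairs.append((int(a_idx[ai]), int(m_idx[mi]), dist))
        unmatched_auto = [int(a_idx[i]) for i in np.flatnonzero(~a_used)]
        unmatched_manual = [int(m_idx[i]) for i in np.flatnonzero(~m_used)]
    else:
        unmatched_auto = [int(i) for i in a_idx]
        unmatched_manual = [int(i) for i in m_idx]
    return MatchResult(pairs, unmatched_auto, unmatched_manual, d)


def compute_metrics(match: MatchResult) -> MetricsRecord:
    """True positive rate, false discovery rate, and Dice's coefficient.

    A rate whose denominator is zero is reported as None rather than 0.
    """
    tpr = match.n_tp / match.n_manual if match.n_manual > 0 else None
    fdr = match.n_fp / match.n_automatic if match.n_automatic > 0 else None
    denom = match.n_manual + match.n_automatic
    dice = 2.0 * match.n_tp / denom if denom > 0 else None
    return MetricsRecord(tpr, fdr, dice)


def cone_density(cones: MarkedCones, image: ConeImage,
                 border_px: float = 0.0, pruned_area: bool = False) -> float:
    """Cone density in cones per mm^2: count / image area.

    The area is the full ROI pixel area converted through the
    microns-per-pixel scale. By default all cones are counted; set
    ``border_px`` to exclude a border strip from the count, and
    ``pruned_area=True`` to shrink the area consistently with that strip
    (off by default: the full-ROI area is the conventional denominator).
    """
    if image.scale is None:
        raise ValueError("image has no microns-per-pixel scale; cannot compute density")
    h, w = image.height, image.width
    pts = np.asarray(cones.points, dtype=float).reshape(-1, 2)
    if border_px > 0:
        pts = pts[prune_border(pts, (h, w), border_px)]
    if pruned_area and border_px > 0:
        h_eff, w_eff = h - 2 * border_px, w - 2 * border_px
        if h_eff <= 0 or w_eff <= 0:
            raise ValueError("border_px too large for the image")
        area = h_eff * w_eff * (image.scale / 1000.0) ** 2
    else:
        area = image.area_mm2()
    return len(pts) / area


def bland_altman(differences: np.ndarray) -> BlandAltman:
    """Mean difference and 95% limits of agreement (sample SD, n-1).

    ``differences`` are per-image paired differences, e.g. manual minus
    automatic cone density.
    """
    diff = np.asarray(differences, dtype=float).ravel()
    if len(diff) < 2:
        raise ValueError("Bland-Altman needs at least 2 paired differences")
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(mean, mean - 1.96 * sd, mean + 1.96 * sd, sd, len(diff))
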