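"""Intensity normalization and labeled-patch extraction for training.

Cone patches are centered on the manual marks. Non-cone patches are sampled
from the Voronoi diagram of the manual marks: the Voronoi edges are the loci
equidistant between neighboring cones — i.e. the space *between* cones — and
one random point per edge gives a non-cone center without requiring any
manual background annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import LineString, box

from .io import ConeImage, MarkedCones

__all__ = [
    "PatchSet",
    "VoronoiEdges",
    "normalize_intensity",
    "voronoi_edges",
    "sample_noncone_points",
    "extract_patches",
    "build_training_set",
    "PATCH",
    "HALF",
]

PATCH = 33
HALF = PATCH // 2  # 16

LABEL_NONCONE, LABEL_CONE = 0, 1


@dataclass
class VoronoiEdges:
    """Finite Voronoi edges of the cone points, clipped to the image rectangle.

    ``edges[i]`` is ((x1, y1), (x2, y2)); ``generators[i]`` holds the indices
    of the two cone points whose cells the edge separates.
    """

    edges: list[tuple[tuple[float, float], tuple[float, float]]]
    generators: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class PatchSet:
    """Labeled 33x33 training patches with per-patch provenance."""

    patches: np.ndarray  # (n, 33, 33) float
    labels: np.ndarray  # (n,) int, 0 = non-cone, 1 = cone
    provenance: list[tuple[str, int, int]] = field(default_factory=list)  # (image id, x, y)

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.patches.ndim != 3 or self.patches.shape[1:] != (PATCH, PATCH):
            raise ValueError(f"patches must be (n, {PATCH}, {PATCH}), got {self.patches.shape}")
        if len(self.patches) != len(self.labels):
            raise ValueError("patches and labels differ in length")
        if self.provenance and len(self.provenance) != len(self.patches):
            raise ValueError("provenance must parallel patches")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def n_cone(self) -> int:
        return int((self.labels == LABEL_CONE).sum())

    @property
    def n_noncone(self) -> int:
        return int((self.labels == LABEL_NONCONE).sum())

    @staticmethod
    def concatenate(sets: Sequence["PatchSet"]) -> "PatchSet":
        if not sets:
            return PatchSet(np.empty((0, PATCH, PATCH)), np.empty(0, dtype=int), [])
        return PatchSet(
            np.concatenate([s.patches for s in sets]),
            np.concatenate([s.labels for s in sets]),
            [p for s in sets for p in s.provenance],
        )


def normalize_intensity(image: ConeImage) -> ConeImage:
    """Linear min-max stretch of the intensities to [0, 255].

    A constant image maps to all zeros (the degenerate guard for the
    zero-range case).
    """
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = (px - lo) * (255.0 / (hi - lo))
    return ConeImage(out, scale=image.scale, modality_tag=image.modality_tag)


def voronoi_edges(cones: MarkedCones, image_dims: tuple[int, int]) -> VoronoiEdges:
    """Voronoi edges of the cone points, clipped to the image rectangle.

    ``image_dims`` is (height, width). Every returned segment separates the
    cells of exactly two cone points; unbounded ridges are clipped at the
    image bounds and kept when the clipped portion has positive length.

    Raises a geometry error for < 3 points or all-collinear points.
    """
    pts = np.asarray(cones.points, dtype=float)
    if len(pts) < 3:
        raise ValueError("Voronoi construction needs at least 3 cone points")
    height, width = image_dims
    try:
        vor = Voronoi(pts)
    except Exception as exc:  # Qhull failure, e.g. collinear input
        raise ValueError(f"degenerate cone configuration for Voronoi diagram: {exc}") from exc

    rect = box(0.0, 0.0, width - 1.0, height - 1.0)
    # length scale for projecting unbounded ridges "to infinity"
    span = 4.0 * max(width, height) + float(np.ptp(pts, axis=0).max())
    center = pts.mean(axis=0)

    edges: list[tuple[tuple[float, float], tuple[float, float]]] = []
    gens: list[tuple[int, int]] = []
    for (p1, p2), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        v1, v2 = ridge
        if v1 == -1 and v2 == -1:
            continue
        if v1 == -1 or v2 == -1:
            known = vor.vertices[v2 if v1 == -1 else v1]
            # direction perpendicular to the generator pair, oriented outward
            t = pts[p2] - pts[p1]
            t /= np.linalg.norm(t)
            n = np.array([-t[1], t[0]])
            midpoint = (pts[p1] + pts[p2]) / 2.0
            if np.dot(midpoint - center, n) < 0:
                n = -n
            far = known + n * span
            seg = LineString([known, far])
        else:
            seg = LineString([vor.vertices[v1], vor.vertices[v2]])
        clipped = seg.intersection(rect)
        if clipped.is_empty or clipped.geom_type != "LineString" or clipped.length <= 0:
            continue
        (x1, y1), (x2, y2) = clipped.coords[0], clipped.coords[-1]
        edges.append(((float(x1), float(y1)), (float(x2), float(y2))))
        gens.append((int(p1), int(p2)))
    return VoronoiEdges(edges=edges, generators=gens)


def sample_noncone_points(edges: VoronoiEdges, rng_seed: int | np.random.Generator,
                          dedupe: bool = True) -> np.ndarray:
    """One random point per Voronoi edge, rounded to the nearest pixel.

    The point is uniform along the (clipped) segment's arc length; an edge
    shorter than one pixel contributes its rounded midpoint. Identical
    rounded pixels from different edges are deduplicated (order-preserving)
    because identical patches carry no extra information. Deterministic for
    a fixed seed.

    Returns an (n, 2) int array of (x, y).
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    pts: list[tuple[int, int]] = []
    for (x1, y1), (x2, y2) in edges.edges:
        length = float(np.hypot(x2 - x1, y2 - y1))
        t = 0.5 if length < 1.0 else float(rng.uniform())
        x = x1 + t * (x2 - x1)
        y = y1 + t * (y2 - y1)
        pts.append((int(round(x)), int(round(y))))
    if not pts:
        return np.empty((0, 2), dtype=int)
    arr = np.asarray(pts, dtype=int)
    if dedupe:
        _, keep = np.unique(arr, axis=0, return_index=True)
        arr = arr[np.sort(keep)]
    return arr


def extract_patches(image: ConeImage, centers: np.ndarray | Sequence[tuple[float, float]],
                    label: int, image_id: str = "") -> PatchSet:
    """33x33 patches around integer-rounded centers; border-crossing ones dropped.

    The center sits at patch index (16, 16). A center whose patch would
    extend outside the image is silently excluded (training-time rule; at
    detection time mirror padding is used instead, see
    :mod:`conedetect.probmap`).
    """
    px = image.pixels
    h, w = px.shape
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    rounded = np.rint(centers).astype(int)
    patches, prov = [], []
    for x, y in rounded:
        if x - HALF < 0 or x + HALF >= w or y - HALF < 0 or y + HALF >= h:
            continue
        patches.append(px[y - HALF:y + HALF + 1, x - HALF:x + HALF + 1])
        prov.append((image_id, int(x), int(y)))
    if not patches:
        return PatchSet(np.empty((0, PATCH, PATCH)), np.empty(0, dtype=int), [])
    arr = np.stack(patches)
    return PatchSet(arr, np.full(len(arr), label, dtype=int), prov)


def build_training_set(
    images: Sequence[ConeImage],
    marks: Sequence[MarkedCones],
    rng_seed: int = 0,
    image_ids: Sequence[str] | None = None,
) -> PatchSet:
    """Full labeled patch set from training images and their manual marks.

    Images are min-max normalized; cone patches come from every in-bounds
    manual mark and non-cone patches from one random point per Voronoi edge.
    Bit-identical for a fixed seed.
    """
    if len(images) != len(marks) or not images:
        raise ValueError("need equally many images and mark lists (>= 1)")
    if image_ids is None:
        image_ids = [f"image{i:03d}" for i in range(len(images))]
    rng = np.random.default_rng(rng_seed)
    parts: list[PatchSet] = []
    for img, m, iid in zip(images, marks, image_ids):
        norm = normalize_intensity(img)
        parts.append(extract_patches(norm, m.points, LABEL_CONE, iid))
        edges = voronoi_edges(m, (img.height, img.width))
        noncone = sample_noncone_points(edges, rng)
        parts.append(extract_patches(norm, noncone, LABEL_NONCONE, iid))
    out = PatchSet.concatenate(parts)
    if out.n_cone == 0:
        raise ValueError("no in-bounds cone patches could be extracted")
    return out
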