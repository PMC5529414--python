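"""Per-pixel cone-probability maps and cone localization.

Detection pipeline: classify the 33x33 patch centered on every pixel of the
normalized image (mirror padding of 16 px at the borders) to form a
probability map; smooth it with a Gaussian of width ``sigma``; take the
extended-maxima transform at height ``H``; label the 8-connected clusters of
the binary result, discard clusters whose maximum smoothed probability falls
below the threshold ``T``; each surviving cluster's unweighted pixel centroid
is one detected cone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import reconstruction

from .cnn import ConeCNN, PATCH_SIZE
from .io import ConeImage, MarkedCones
from .preprocess import normalize_intensity

__all__ = [
    "ProbabilityMap",
    "DetectionParams",
    "ClusterSet",
    "CONFOCAL_PARAMS",
    "SPLITDETECTOR_PARAMS",
    "MIXED_PARAMS",
    "compute_probability_map",
    "smooth_map",
    "regional_maxima",
    "extended_maxima",
    "label_clusters",
    "localize_cones",
    "detect_cones",
]

_HALF = PATCH_SIZE // 2  # 16
_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass(frozen=True)
class DetectionParams:
    """Post-processing triple (sigma, H, T)."""

    sigma: float  # Gaussian smoothing std, px
    h: float  # extended-maxima height
    t: float  # cluster probability threshold

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.h < 0:
            raise ValueError("H must be >= 0")
        if not 0 <= self.t <= 1:
            raise ValueError("T must lie in [0, 1]")

    def astuple(self) -> tuple[float, float, float]:
        return (self.sigma, self.h, self.t)


#: published optima for the three trained networks
CONFOCAL_PARAMS = DetectionParams(1.3, 0.0, 0.3)
SPLITDETECTOR_PARAMS = DetectionParams(2.0, 0.1, 0.5)
MIXED_PARAMS = DetectionParams(0.4, 0.25, 0.9)


@dataclass
class ProbabilityMap:
    """Per-pixel cone probability, same height/width as the source image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("probability map must be 2-D and non-empty")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("probability values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClusterSet:
    """8-connected clusters of a binary mask, with per-cluster statistics."""

    labels: np.ndarray  # int label image, 0 = background
    n: int
    max_values: np.ndarray  # (n,) max of the smoothed map within each cluster
    centroids: np.ndarray  # (n, 2) unweighted pixel centroids as (x, y)
    sizes: np.ndarray  # (n,) pixel counts


def extract_pixel_patches(image: ConeImage) -> np.ndarray:
    """The 33x33 patch around every pixel, mirror-padded at the borders.

    Padding duplicates the edge pixel (half-sample symmetric reflection) by
    16 px on each side. Returns an (h*w, 33, 33) float32 array in row-major
    pixel order.
    """
    px = image.pixels.astype(np.float32)
    padded = np.pad(px, _HALF, mode="symmetric")
    win = np.lib.stride_tricks.sliding_window_view(padded, (PATCH_SIZE, PATCH_SIZE))
    return win.reshape(-1, PATCH_SIZE, PATCH_SIZE)  # copies into contiguous memory


def compute_probability_map(net: ConeCNN, image: ConeImage,
                            batch_size: int = 64) -> ProbabilityMap:
    """Classify the patch centered at every pixel of a *normalized* image."""
    h, w = image.pixels.shape
    patches = extract_pixel_patches(image)
    probs = net.predict_proba(patches, batch_size=batch_size)
    return ProbabilityMap(probs.reshape(h, w))


def smooth_map(pmap: ProbabilityMap, sigma: float) -> ProbabilityMap:
    """Gaussian smoothing (reflective boundary, kernel truncated at 4 sigma).

    ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ProbabilityMap(pmap.values.copy())
    out = ndimage.gaussian_filter(pmap.values, sigma=sigma, mode="reflect", truncate=4.0)
    return ProbabilityMap(np.clip(out, 0.0, 1.0))


def regional_maxima(values: np.ndarray) -> np.ndarray:
    """Boolean mask of regional maxima (8-connectivity).

    A regional maximum is a connected plateau of equal values whose every
    outside neighbor is strictly lower; a constant image is one maximal
    region covering everything. Implemented by flood-filling "dominated"
    status through equal-valued plateaus.
    """
    values = np.asarray(values, dtype=np.float64)
    neigh_max = ndimage.maximum_filter(values, size=3, mode="constant", cval=-np.inf)
    bad = neigh_max > values  # has a strictly greater neighbor
    while True:
        marked = np.where(bad, values, -np.inf)
        spread = ndimage.maximum_filter(marked, size=3, mode="constant", cval=-np.inf)
        new_bad = spread >= values  # an equal-valued (or greater) bad neighbor
        if np.array_equal(new_bad, bad):
            return ~bad
        bad = new_bad


def extended_maxima(pmap: ProbabilityMap | np.ndarray, h: float) -> np.ndarray:
    """Extended-maxima transform: regional maxima of the H-maxima transform.

    The H-maxima transform is the morphological reconstruction by dilation of
    ``map - H`` under ``map`` (8-connectivity), which suppresses any maximum
    rising less than ``H`` above its surroundings; ``H = 0`` reduces to plain
    regional maxima.
    """
    if h < 0:
        raise ValueError("H must be >= 0")
    values = pmap.values if isinstance(pmap, ProbabilityMap) else np.asarray(pmap, float)
    if h > 0:
        values = reconstruction(values - h, values, method="dilation",
                                footprint=np.ones((3, 3)))
    return regional_maxima(values)


def label_clusters(mask: np.ndarray, smoothed: ProbabilityMap | np.ndarray,
                   weighted: bool = False) -> ClusterSet:
    """Label the 8-connected clusters of ``mask`` and compute their statistics.

    ``weighted=True`` uses probability-weighted centroids instead of the
    default unweighted pixel centroids (the cluster "center" is ambiguous in
    the original description; unweighted is the simplest reading).
    """
    values = smoothed.values if isinstance(smoothed, ProbabilityMap) else np.asarray(smoothed)
    if mask.shape != values.shape:
        raise ValueError("mask and map shapes differ")
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return ClusterSet(labels, 0, np.empty(0), np.empty((0, 2)), np.empty(0, dtype=int))
    idx = np.arange(1, n + 1)
    max_values = ndimage.maximum(values, labels=labels, index=idx)
    weights = values * mask if weighted else mask
    cy, cx = zip(*ndimage.center_of_mass(weights, labels=labels, index=idx))
    centroids = np.column_stack([cx, cy]).astype(float)
    sizes = ndimage.sum_labels(mask, labels=labels, index=idx).astype(int)
    return ClusterSet(labels, n, np.atleast_1d(max_values), centroids, sizes)


def localize_cones(mask: np.ndarray, smoothed: ProbabilityMap | np.ndarray,
                   t: float, weighted: bool = False) -> MarkedCones:
    """Cone centers from the extended-maxima mask.

    Clusters whose maximum smoothed probability is below ``t`` are removed;
    each surviving cluster contributes its (by default unweighted) pixel
    centroid (fractional coordinates allowed).
    """
    cs = label_clusters(mask, smoothed, weighted=weighted)
    keep = cs.max_values >= t
    pts = cs.centroids[keep]
    if len(pts) > 1:
        # distinct clusters can tie to the exact same centroid on symmetric
        # toy maps; coincident detections collapse to one
        _, first = np.unique(pts, axis=0, return_index=True)
        pts = pts[np.sort(first)]
    return MarkedCones(pts, source="automatic")


def detect_cones(image: ConeImage, net: ConeCNN, params: DetectionParams,
                 pmap: ProbabilityMap | None = None) -> MarkedCones:
    """Full detection on a raw image: normalize, map, smooth, extended maxima,
    cluster filtering, centroids.

    ``pmap`` may be supplied to reuse a precomputed probability map (it is the
    expensive stage); it must correspond to the normalized image.
    """
    if pmap is None:
        pmap = compute_probability_map(net, normalize_intensity(image))
    smoothed = smooth_map(pmap, params.sigma)
    mask = extended_maxima(smoothed, params.h)
    return localize_cones(mask, smoothed, params.t)
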