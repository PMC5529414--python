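"""Reading and writing of images, cone coordinate lists, and trained-model bundles.

Coordinate convention (used by every module in this package): ``x`` is the
column index, ``y`` the row index, both 0-based, with pixel centers at integer
coordinates. Coordinates are stored as floats because detected cone positions
(cluster centroids) are fractional even though manual marks are usually
pixel-aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ConeImage",
    "MarkedCones",
    "ModelBundle",
    "FormatError",
    "load_image",
    "load_coordinates",
    "save_coordinates",
    "save_model",
    "load_model",
]


class FormatError(ValueError):
    """Raised for malformed image / coordinate / model files."""


@dataclass
class ConeImage:
    """A grayscale AOSLO image, optionally with a microns-per-pixel scale."""

    pixels: np.ndarray
    scale: float | None = None  # microns per pixel
    modality_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError(f"expected a non-empty 2-D image, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("image contains non-finite pixels")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"scale must be > 0 microns/pixel, got {self.scale}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def area_mm2(self) -> float:
        """Image area in mm^2 (requires a microns-per-pixel scale)."""
        if self.scale is None:
            raise ValueError("image has no microns-per-pixel scale; cannot compute area")
        return self.height * self.width * (self.scale / 1000.0) ** 2


@dataclass
class MarkedCones:
    """Cone coordinates for one image, either manual ground truth or detections."""

    points: np.ndarray  # (n, 2) float array of (x, y)
    source: str = "manual"  # "manual" | "automatic"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = np.empty((0, 2))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("cone coordinates must be finite")
        if len(pts) != len(np.unique(pts, axis=0)):
            raise ValueError("duplicate cone coordinates")
        if self.source not in ("manual", "automatic"):
            raise ValueError(f"source must be 'manual' or 'automatic', got {self.source!r}")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def validate_bounds(self, height: int, width: int) -> None:
        """Check every point lies inside the image rectangle [0, w-1] x [0, h-1]."""
        if len(self) == 0:
            return
        x, y = self.points[:, 0], self.points[:, 1]
        bad = (x < 0) | (x > width - 1) | (y < 0) | (y > height - 1)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"cone {i} at {tuple(self.points[i])} outside image bounds {width}x{height}"
            )


def load_image(path: str | Path, scale: float | None = None,
               modality_tag: str = "unknown") -> ConeImage:
    """Load a TIFF/PNG image as a float grayscale :class:`ConeImage`.

    RGB input is converted to luminance by channel mean; the input dynamic
    range is preserved (no rescaling happens here).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated / unreadable file
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    if arr.ndim != 2 or arr.size == 0:
        raise FormatError(f"{path}: expected a 2-D grayscale or RGB image, got shape {arr.shape}")
    return ConeImage(arr, scale=scale, modality_tag=modality_tag)


def load_coordinates(path: str | Path, source: str = "manual",
                     image_dims: tuple[int, int] | None = None) -> MarkedCones:
    """Load a cone coordinate CSV with header ``x,y`` (pixels, possibly fractional).

    Parameters
    ----------
    image_dims:
        Optional ``(height, width)``; when given, out-of-bounds points raise.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise IOError(f"could not read coordinate file {path}: {exc}") from exc
    if not {"x", "y"}.issubset(df.columns):
        raise FormatError(f"{path}: coordinate CSV must have columns 'x' and 'y'")
    pts = df[["x", "y"]].to_numpy(dtype=np.float64)
    if len(pts) != len(np.unique(pts, axis=0)):
        raise ValueError(f"{path}: duplicate coordinate rows")
    cones = MarkedCones(pts, source=source)
    if image_dims is not None:
        cones.validate_bounds(*image_dims)
    return cones


def save_coordinates(cones: MarkedCones, path: str | Path) -> None:
    """Write coordinates as a CSV with header ``x,y`` (UTF-8, LF line endings).

    Values are written with :func:`repr` precision so that
    ``load_coordinates(save_coordinates(c))`` is bit-exact.
    """
    path = Path(path)
    lines = ["x,y"]
    for x, y in cones.points:
        lines.append(f"{_fmt(x)},{_fmt(y)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def _fmt(v: float) -> str:
    # shortest repr that round-trips float64
    return np.format_float_positional(v, unique=True, trim="0")


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A trained network plus the configuration needed to reproduce/apply it.

    Serialized as a directory: ``weights.npz`` (all arrays) + ``meta.json``
    (architecture id, normalization convention, training config snapshot, and
    detection parameters), so that the bundle is portable and diff-able.
    """

    arrays: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    NORMALIZATION_ID = "minmax-0-255"


def save_model(bundle: ModelBundle, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **bundle.arrays)
    (path / "meta.json").write_text(json.dumps(bundle.meta, indent=2, sort_keys=True) + "\n")


def load_model(path: str | Path, expected_shapes: dict[str, tuple] | None = None) -> ModelBundle:
    """Load a model bundle, validating array shapes against the architecture.

    ``expected_shapes`` defaults to the canonical cone-CNN layer shapes
    (see :func:`conedetect.cnn.parameter_shapes`).
    """
    path = Path(path)
    npz = np.load(path / "weights.npz")
    arrays = {k: npz[k] for k in npz.files}
    meta = json.loads((path / "meta.json").read_text())
    if expected_shapes is None:
        from .cnn import parameter_shapes
        expected_shapes = parameter_shapes()
    for name, shape in expected_shapes.items():
        if name not in arrays:
            raise FormatError(f"model bundle missing array {name!r}")
        if tuple(arrays[name].shape) != tuple(shape):
            raise FormatError(
                f"model bundle array {name!r} has shape {arrays[name].shape}, "
                f"expected {tuple(shape)}"
            )
    return ModelBundle(arrays=arrays, meta=meta)
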