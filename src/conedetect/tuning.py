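"""Automatic selection of the detection parameters (sigma, H, T).

The triple is chosen by exhaustive grid search maximizing the mean per-image
Dice's coefficient against the manual marks of the training images, using
their precomputed probability maps (CNN inference is the expensive stage;
smoothing, extended maxima and thresholding are cheap in comparison, so the
grid can be dense).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MarkedCones
from .metrics import DEFAULT_BORDER_PX, compute_metrics, match_cones, match_radius
from .probmap import (DetectionParams, ProbabilityMap, extended_maxima,
                      label_clusters, localize_cones, smooth_map)

__all__ = ["ParamGrid", "TuningResult", "default_grid", "optimize_params"]


def _steps(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step))
    return tuple(round(lo + i * step, 10) for i in range(n + 1))


@dataclass(frozen=True)
class ParamGrid:
    """Candidate values for sigma, H and T; searched as a Cartesian product."""

    sigmas: tuple[float, ...]
    hs: tuple[float, ...]
    ts: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (self.sigmas and self.hs and self.ts):
            raise ValueError("all three candidate lists must be non-empty")
        if min(self.sigmas) < 0 or min(self.hs) < 0:
            raise ValueError("sigma and H candidates must be >= 0")
        if min(self.ts) < 0 or max(self.ts) > 1:
            raise ValueError("T candidates must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sigmas) * len(self.hs) * len(self.ts)

    def to_dict(self) -> dict:
        return {"sigmas": list(self.sigmas), "hs": list(self.hs), "ts": list(self.ts)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParamGrid":
        return cls(tuple(d["sigmas"]), tuple(d["hs"]), tuple(d["ts"]))


def default_grid() -> ParamGrid:
    """sigma in {0, 0.1, ..., 3.0}, H in {0, 0.05, ..., 0.5}, T in {0.1, ..., 0.9}.

    The steps are chosen so that the published optima for all three network
    variants — (1.3, 0, 0.3), (2, 0.1, 0.5) and (0.4, 0.25, 0.9) — are exact
    grid points.
    """
    return ParamGrid(_steps(0.0, 3.0, 0.1), _steps(0.0, 0.5, 0.05), _steps(0.1, 0.9, 0.1))


@dataclass
class TuningResult:
    params: DetectionParams
    mean_dice: float
    scores: pd.DataFrame = field(repr=False)  # one row per grid point


def optimize_params(
    probmaps: list[ProbabilityMap],
    manuals: list[MarkedCones],
    grid: ParamGrid | None = None,
    border: float = DEFAULT_BORDER_PX,
) -> TuningResult:
    """Exhaustive grid search for the (sigma, H, T) maximizing mean Dice.

    Ties break toward the smallest sigma, then smallest H, then *largest* T
    (the most conservative cluster filter among equivalent optima). The full
    score table is returned for audit.
    """
    if grid is None:
        grid = default_grid()
    if not probmaps or len(probmaps) != len(manuals):
        raise ValueError("need equally many probability maps and manual mark lists (>= 1)")
    radii = [match_radius(m) for m in manuals]
    dims = [pm.shape for pm in probmaps]

    rows = []
    best: tuple[float, DetectionParams] | None = None
    for sigma in sorted(grid.sigmas):
        smoothed = [smooth_map(pm, sigma) for pm in probmaps]
        for h in sorted(grid.hs):
            clustered = [label_clusters(extended_maxima(sm, h), sm) for sm in smoothed]
            for t in sorted(grid.ts, reverse=True):
                dices = []
                for cs, manual, d, dim in zip(clustered, manuals, radii, dims):
                    pts = cs.centroids[cs.max_values >= t]
                    if len(pts) > 1:
                        _, first = np.unique(pts, axis=0, return_index=True)
                        pts = pts[np.sort(first)]
                    auto = MarkedCones(pts, source="automatic")
                    rec = compute_metrics(match_cones(auto, manual, d, dim, border))
                    dices.append(rec.dice if rec.dice is not None else 0.0)
                mean_dice = float(np.mean(dices))
                rows.append({"sigma": sigma, "h": h, "t": t, "mean_dice": mean_dice})
                if best is None or mean_dice > best[0]:
                    best = (mean_dice, DetectionParams(sigma, h, t))
    scores = pd.DataFrame(rows)
    return TuningResult(params=best[1], mean_dice=best[0], scores=scores)
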