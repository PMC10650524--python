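"""Observation windows, point patterns, and nearest-neighbor distances.

The geometric substrate for the stomatal-pattern statistics: a rectangular
observation window (the microscope field of view, in μm), a set of stomatal
center coordinates inside it, and per-point nearest-neighbor distances (NND)
computed either with plain Euclidean distances — the measurement convention
for real leaf data — or with toroidal (periodic) distances, which remove
edge bias and are used to validate simulations against closed-form theory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: Below this point count the O(n^2) scan is used; above it, a k-d tree.
#: Behavior is identical either way (verified by the brute-force oracle tests).
_BRUTE_FORCE_MAX = 64


@dataclass(frozen=True)
class ObservationWindow:
    """Rectangular observation domain, dimensions in μm.

    The default is the study's microscope field of view, 1.2 mm x 0.9 mm,
    i.e. the coordinate domain [0, 1200] x [0, 900] μm with the origin at
    one corner. All statistics computed here are invariant to which corner
    is chosen, so no image-axis flip is ever applied.
    """

    width: float = 1200.0
    height: float = 900.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.width) and np.isfinite(self.height)):
            raise ValueError("window dimensions must be finite")
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"window dimensions must be positive, got "
                f"{self.width} x {self.height}"
            )

    @property
    def area_um2(self) -> float:
        """Window area in μm² (default window: 1.08e6 μm²)."""
        return self.width * self.height

    @property
    def area_mm2(self) -> float:
        """Window area in mm² (default window: 1.08 mm²)."""
        return self.area_um2 / 1.0e6


#: The study's field of view.
DEFAULT_WINDOW = ObservationWindow(1200.0, 900.0)


class PointPattern:
    """Stomatal centers within one observation window.

    Parameters
    ----------
    points : array-like of shape (n, 2)
        (x, y) coordinates in μm, with 0 <= x <= width and 0 <= y <= height.
    window : ObservationWindow
        The domain the points live in.
    label : object, optional
        Section metadata (species / leaf / layer / position); carried along
        untouched. See :class:`stomapattern.io.SectionLabel`.
    """

    def __init__(self, points, window: ObservationWindow = DEFAULT_WINDOW,
                 label: Optional[object] = None):
        pts = np.asarray(points, dtype=float)
        if pts.size == 0:
            pts = np.empty((0, 2), dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (n, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite (no NaN/inf)")
        if pts.size and (
            pts[:, 0].min() < 0 or pts[:, 0].max() > window.width
            or pts[:, 1].min() < 0 or pts[:, 1].max() > window.height
        ):
            bad = np.flatnonzero(
                (pts[:, 0] < 0) | (pts[:, 0] > window.width)
                | (pts[:, 1] < 0) | (pts[:, 1] > window.height)
            )
            raise ValueError(
                f"{bad.size} point(s) outside the {window.width} x "
                f"{window.height} μm window (first offending index: {bad[0]})"
            )
        self.points = pts
        self.points.setflags(write=False)
        self.window = window
        self.label = label

    @property
    def n(self) -> int:
        """Number of points (stomata) in the window."""
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = f", label={self.label!r}" if self.label is not None else ""
        return (f"PointPattern(n={self.n}, window={self.window.width:g}x"
                f"{self.window.height:g} μm{lab})")


def _nnd_euclidean(pts: np.ndarray) -> np.ndarray:
    n = pts.shape[0]
    if n <= _BRUTE_FORCE_MAX:
        d = squareform(pdist(pts))
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    return dist[:, 1]


def _nnd_toroidal(pts: np.ndarray, window: ObservationWindow) -> np.ndarray:
    box = (window.width, window.height)
    # cKDTree's periodic mode needs coordinates in [0, box); points exactly
    # on the far edge wrap to 0 (the same location on the torus).
    wrapped = np.mod(pts, box)
    tree = cKDTree(wrapped, boxsize=box)
    dist, _ = tree.query(wrapped, k=2)
    return dist[:, 1]


def nearest_neighbor_distances(pattern: PointPattern,
                               metric: str = "euclidean") -> np.ndarray:
    """Distance from each point to its nearest neighbor, in μm.

    Parameters
    ----------
    pattern : PointPattern
        At least two points are required; with fewer, the nearest-neighbor
        distance is undefined.
    metric : {"euclidean", "toroidal"}
        "euclidean" is the plain within-window distance used for leaf data
        (no edge correction). "toroidal" wraps both axes periodically and
        exists to validate simulations free of edge bias; wrapping can only
        shorten distances, so toroidal NND <= Euclidean NND pointwise.

    Returns
    -------
    ndarray of shape (n,)
        Element ``i`` is ``min over j != i`` of the chosen distance between
        points ``i`` and ``j``.
    """
    if pattern.n < 2:
        raise ValueError(
            f"NND undefined: need at least 2 points, got {pattern.n}"
        )
    if metric == "euclidean":
        out = _nnd_euclidean(pattern.points)
    elif metric == "toroidal":
        out = _nnd_toroidal(pattern.points, pattern.window)
    else:
        raise ValueError(f"unknown metric {metric!r}; "
                         "expected 'euclidean' or 'toroidal'")
    if np.any(out == 0.0):
        # Coincident stomata are physically impossible but can occur in
        # hand-clicked coordinate tables; keep them, but say so.
        logger.warning(
            "pattern%s contains %d duplicate point(s) (zero NND)",
            f" {pattern.label}" if pattern.label is not None else "",
            int(np.count_nonzero(out == 0.0)),
        )
    return out


def mean_nearest_neighbor_distance(pattern: PointPattern,
                                   metric: str = "euclidean") -> float:
    """Mean nearest-neighbor distance (MNND) of the pattern, in μm."""
    return float(nearest_neighbor_distances(pattern, metric=metric).mean())
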