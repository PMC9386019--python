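"""Per-cell geometric measurements.

A wing cell is measured from its (simplified) boundary polygon:

* ``area``     — absolute value of the signed shoelace sum
  ``1/2 * sum(x_i * y_{i+1} - x_{i+1} * y_i)`` over the closed vertex list;
* ``length``   — the maximum Euclidean distance between two boundary points;
* ``width``    — area / length, exactly;
* ``centroid`` — the area-weighted polygon centroid.

All quantities are computed in Cartesian coordinates (``x = col``,
``y = height - 1 - row``) and are invariant to translation and rotation of
the wing in the image.  An optional scale (physical length per pixel)
converts px and px^2 to physical units.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError


@dataclass(frozen=True)
class ScaleSpec:
    """Physical length of one pixel edge, e.g. ``ScaleSpec(0.1, "mm")``."""

    length_per_pixel: float
    unit: str = "mm"

    def __post_init__(self):
        if not (self.length_per_pixel > 0 and np.isfinite(self.length_per_pixel)):
            raise DegenerateInputError("length_per_pixel must be positive and finite")


@dataclass
class CellMorphometry:
    cell_id: int
    area: float
    length: float
    width: float
    centroid: tuple
    unit: str = "px"


@dataclass
class DistributionSummary:
    metric: str
    bin_edges: np.ndarray
    counts: np.ndarray
    values: dict  # cell_id -> value, for contour rendering
    unit: str = "px"


def pixels_to_cartesian(chain, height: int) -> np.ndarray:
    """Convert (row, col) pixel coordinates to (x, y) with y up."""
    chain = np.asarray(chain, dtype=float)
    return np.stack([chain[:, 1], (height - 1) - chain[:, 0]], axis=1)


def polygon_area(vertices) -> float:
    """Shoelace area of a simple closed polygon (orientation-independent)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise DegenerateInputError("polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)


def polygon_centroid(vertices) -> tuple:
    """Area-weighted centroid of a simple closed polygon."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        raise DegenerateInputError("polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = np.sum(cross) / 2.0
    if a == 0:
        raise DegenerateInputError("zero-area polygon has no centroid")
    cx = np.sum((x + np.roll(x, -1)) * cross) / (6.0 * a)
    cy = np.sum((y + np.roll(y, -1)) * cross) / (6.0 * a)
    return (float(cx), float(cy))


def cell_length(boundary) -> float:
    """Maximum pairwise distance between boundary points.

    Exact: reduces to the convex hull first (the diameter is attained at
    hull vertices), then takes the maximum over all hull-vertex pairs.
    """
    pts = np.unique(np.asarray(boundary, dtype=float), axis=0)
    if len(pts) < 2:
        raise DegenerateInputError("length needs at least 2 distinct points")
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # collinear: brute force below is still exact
    return float(pdist(pts).max())


def cell_width(area: float, length: float) -> float:
    """Cell width: the ratio of cell area to cell length."""
    if length <= 0:
        raise DegenerateInputError("length must be positive")
    return area / length


def measure_polygon(vertices, cell_id: int = 0,
                    scale: ScaleSpec | None = None) -> CellMorphometry:
    """All morphometrics of one cell polygon, optionally in physical units."""
    area = polygon_area(vertices)
    length = cell_length(vertices)
    centroid = polygon_centroid(vertices)
    s = scale.length_per_pixel if scale else 1.0
    unit = scale.unit if scale else "px"
    area, length = area * s * s, length * s
    width = cell_width(area, length)
    if width > length:
        warn(f"cell {cell_id}: width {width:.3g} exceeds length {length:.3g}",
             stacklevel=2)
    return CellMorphometry(cell_id=cell_id, area=area, length=length, width=width,
                           centroid=(centroid[0] * s, centroid[1] * s), unit=unit)


def measure_cells(boundaries, height: int,
                  scale: ScaleSpec | None = None) -> list:
    """Morphometrics for a list of simplified cell boundaries (pixel coords).

    *boundaries* maps cell id -> (k, 2) ``(row, col)`` vertex arrays (e.g.
    ``SimplifiedBoundary.vertices``); they are converted to Cartesian first.
    """
    out = []
    for cell_id, chain in boundaries.items():
        verts = pixels_to_cartesian(chain, height)
        out.append(measure_polygon(verts, cell_id=cell_id, scale=scale))
    return out


def summarize(cells, metric: str, n_bins: int = 10,
              scale: ScaleSpec | None = None) -> DistributionSummary:
    """Equal-width histogram of one metric over all cells.

    Bins span [min, max] of the data; bins are right-open except the last
    (NumPy's convention).  Cell values are kept per id for contour maps.
    A *scale* converts pixel-valued cells to physical units here (area by
    the square of the factor, length and width linearly); cells already
    measured in physical units are left untouched.
    """
    if not cells:
        raise DegenerateInputError("no cells to summarise")
    if metric not in ("area", "length", "width"):
        raise ValueError(f"unknown metric {metric!r}")
    if n_bins < 1:
        raise DegenerateInputError("n_bins must be >= 1")
    factor, unit = 1.0, cells[0].unit
    if scale is not None and unit == "px":
        factor = scale.length_per_pixel ** (2 if metric == "area" else 1)
        unit = scale.unit
    values = {c.cell_id: getattr(c, metric) * factor for c in cells}
    data = np.array(list(values.values()), dtype=float)
    counts, edges = np.histogram(data, bins=n_bins)
    return DistributionSummary(metric=metric, bin_edges=edges, counts=counts,
                               values=values, unit=unit)
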