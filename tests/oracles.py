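"""Brute-force oracles shared across test modules.

Each oracle is deliberately naive (enumeration, counting, closed form) and
independent of the implementation path it checks.
"""

import math

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon


def random_lattice_polygon(rng, n_max=12, radius=15):
    """Random simple lattice polygon (star-shaped around the origin)."""
    while True:
        n = rng.integers(4, n_max)
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        radii = rng.uniform(3, radius, n)
        pts = np.stack([np.round(radii * np.cos(angles)),
                        np.round(radii * np.sin(angles))], axis=1)
        pts = pts[np.any(np.diff(np.vstack([pts, pts[:1]]), axis=0) != 0,
                         axis=1)]
        if len(pts) >= 3 and ShapelyPolygon(pts).is_valid:
            return pts


def picks_theorem_area(pts):
    """Lattice-polygon area oracle: I + B/2 - 1 by brute-force counting."""
    poly = ShapelyPolygon(pts)
    B = 0
    for a, b in zip(pts, np.vstack([pts[1:], pts[:1]])):
        B += math.gcd(int(abs(b[0] - a[0])), int(abs(b[1] - a[1])))
    xmin, ymin, xmax, ymax = (int(v) for v in poly.bounds)
    xs, ys = np.meshgrid(np.arange(xmin, xmax + 1), np.arange(ymin, ymax + 1))
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel())
    return int(inside.sum()) + B / 2.0 - 1


def euler_holes(mask):
    """Topology oracle: (8-connected components, enclosed holes)."""
    comps = ndimage.label(mask, structure=np.ones((3, 3)))[1]
    lab, n = ndimage.label(~mask)  # 4-connected background
    border = set(np.unique(np.concatenate(
        [lab[0], lab[-1], lab[:, 0], lab[:, -1]]))) - {0}
    return comps, n - len(border)
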