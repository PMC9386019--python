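"""Ramer-Douglas-Peucker boundary simplification.

Traced boundary chains carry one vertex per pixel, far more than geometry
export or morphometrics need.  RDP keeps only the critical points: given a
tolerance ``epsilon``, every discarded point is guaranteed to lie within
``epsilon`` (perpendicular point-to-segment distance) of the simplified
polyline, i.e. the directed Hausdorff distance from the original chain to
the simplified one is at most ``epsilon``.  A smaller ``epsilon`` keeps more
points; ``epsilon = 0`` is the identity.

Closed chains are split at two anchors — the lexicographically first point
and the point farthest from it — and each half simplified as an open chain,
so the guarantee carries over to closed contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError

DEFAULT_EPSILON = 1.0


@dataclass
class SimplifiedBoundary:
    """RDP-reduced boundary: an ordered subset of the source chain."""

    vertices: np.ndarray     # (k, 2), subset of the source chain, source order
    indices: np.ndarray      # (k,) indices into the source chain
    source_id: int
    epsilon: float
    closed: bool
    arc_accuracy: float      # percent similarity to the source chain

    def __len__(self):
        return len(self.vertices)


def _point_segment_distances(points, a, b):
    """Perpendicular distance of *points* to segment a-b (not the infinite line)."""
    points = np.asarray(points, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _rdp_open(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Indices kept by RDP on an open chain (endpoints always kept).

    Iterative divide-and-conquer: for each span, the farthest point from the
    chord is kept iff its distance exceeds epsilon; ties go to the smaller
    index (``argmax`` returns the first maximum), so output is deterministic.
    """
    n = len(points)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        d = _point_segment_distances(points[i + 1:j], points[i], points[j])
        k = int(np.argmax(d))
        if d[k] > epsilon:
            m = i + 1 + k
            keep[m] = True
            stack.append((i, m))
            stack.append((m, j))
    return np.flatnonzero(keep)


def rdp_simplify(chain, epsilon: float = DEFAULT_EPSILON, closed: bool = True,
                 source_id: int = 0) -> SimplifiedBoundary:
    """Simplify a boundary chain with tolerance *epsilon*.

    For closed chains the cyclic order of the input is preserved and the
    first output vertex is the lexicographically smallest point of the chain.
    ``epsilon = 0`` returns the chain unchanged (identity limit).
    """
    pts = np.asarray(chain, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateInputError("chain must be an (n, 2) array")
    n = len(pts)
    if epsilon < 0 or not np.isfinite(epsilon):
        raise DegenerateInputError(f"epsilon must be finite and >= 0, got {epsilon}")
    if n < (3 if closed else 2):
        raise DegenerateInputError(
            f"chain of {n} points too short for {'closed' if closed else 'open'} RDP"
        )

    if epsilon == 0:
        idx = np.arange(n)
    elif not closed:
        idx = _rdp_open(pts, epsilon)
    else:
        # rotate so the lexicographically first point is the split anchor
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        shift = int(order[0])
        rolled = np.roll(pts, -shift, axis=0)
        far = int(np.argmax(np.linalg.norm(rolled - rolled[0], axis=1)))
        if far == 0:  # all points coincide
            idx = np.array([0])
        else:
            first = _rdp_open(rolled[: far + 1], epsilon)
            wrap = np.vstack([rolled[far:], rolled[:1]])
            second = _rdp_open(wrap, epsilon) + far
            second[second == n] = 0
            kept = np.unique(np.concatenate([first, second]))
            idx = (kept + shift) % n
            idx = np.sort(idx)
            # restore cyclic order starting from the anchor
            anchor = np.flatnonzero(idx == shift)[0]
            idx = np.roll(idx, -anchor)
    accuracy = arc_accuracy(pts, pts[idx], closed=closed)
    return SimplifiedBoundary(vertices=pts[idx], indices=idx, source_id=source_id,
                              epsilon=float(epsilon), closed=closed,
                              arc_accuracy=accuracy)


def polyline_deviation(original, simplified, closed: bool = True) -> float:
    """Directed Hausdorff distance from *original* points to the simplified
    polyline (the quantity the RDP epsilon bounds)."""
    original = np.asarray(original, dtype=float)
    simplified = np.asarray(simplified, dtype=float)
    if len(simplified) == 1:
        return float(np.max(np.linalg.norm(original - simplified[0], axis=1)))
    segs = list(zip(simplified[:-1], simplified[1:]))
    if closed and len(simplified) > 2:
        segs.append((simplified[-1], simplified[0]))
    dmin = np.full(len(original), np.inf)
    for a, b in segs:
        np.minimum(dmin, _point_segment_distances(original, a, b), out=dmin)
    return float(dmin.max())


def chain_diameter(chain) -> float:
    """Maximum pairwise distance between chain points (via the convex hull)."""
    pts = np.unique(np.asarray(chain, dtype=float), axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear input
            pass
    return float(pdist(pts).max())


def arc_accuracy(original, simplified, closed: bool = True) -> float:
    """Similarity (percent) between a chain and its simplification.

    Defined as ``100 * (1 - d_H / D)`` clamped to [0, 100], where ``d_H`` is
    the directed Hausdorff distance from the original points to the
    simplified polyline and ``D`` the original chain's diameter, making the
    score scale-invariant; 100 means the simplified curve reproduces the
    original exactly.
    """
    D = chain_diameter(original)
    if D == 0:
        raise DegenerateInputError("zero-diameter chain: accuracy undefined")
    d_h = polyline_deviation(original, simplified, closed=closed)
    return float(np.clip(100.0 * (1.0 - d_h / D), 0.0, 100.0))
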