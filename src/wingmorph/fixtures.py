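"""Synthetic wing fixtures with exact ground truth.

Real wing photographs cannot ship with a test suite, and even if they could
their true cell polygons and junction coordinates are unknown.  The
generator builds wing-like binary images from analytic geometry so that
every later stage can be checked against exact ground truth:

* the silhouette is an ellipse (elongated, like a generic wing planform);
* venation is a bounded Voronoi tessellation of points sampled inside the
  silhouette, rendered as black strokes of constant width — Voronoi cells
  are convex, non-overlapping, and partition the interior, just as veins
  partition a wing into cells;
* ground-truth junctions are the Voronoi vertices inside the silhouette
  plus the points where ridges meet the outline;
* damage (holes) is cut by erasing pixels inside a hole polygon and drawing
  the torn rim as a stroke.

Rendering is binary — a pixel is black iff its centre lies inside the
stroke band — with no anti-aliasing, so pixel-level oracles are exact.
Because boundary chains pass through black pixel centres (about half a
pixel inside the stroke band), truth cell polygons are the Voronoi cells
eroded by ``(vein_width - 1) / 2`` rather than ``vein_width / 2``.

All randomness flows through one seeded ``numpy.random.Generator``; the same
``(seed, params)`` always reproduces the identical fixture bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.optimize import linear_sum_assignment
from scipy.spatial import Voronoi
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Point, Polygon as ShapelyPolygon
from shapely.ops import unary_union

from .errors import GenerationError

DEFAULT_SIZE = (300, 450)       # (rows, cols)
DEFAULT_VEIN_WIDTH = 3
MIN_CELL_AREA = 250.0           # analytic px^2; smaller cells are rejected
MIN_JUNCTION_SEP = 7.0          # px between ground-truth junctions
                                # (> 2x the 3 px junction match tolerance)
SILHOUETTE_VERTICES = 256


@dataclass
class WingFixture:
    """A rendered synthetic wing plus its analytic ground truth.

    Truth polygons are (k, 2) arrays in ``(row, col)`` coordinates; the
    junction array rows are ``(row, col)`` too.
    """

    image: np.ndarray                 # bool, True = white
    silhouette: np.ndarray            # outline polygon (row, col)
    cells: list                       # truth cell polygons
    junctions: np.ndarray             # (m, 2) float
    seed: int
    params: dict
    holes: list = field(default_factory=list)
    secondary: np.ndarray | None = None
    vein_lines: object = None         # shapely geometry of vein centrelines


def _ellipse(center_rc, semi_row, semi_col, n=SILHOUETTE_VERTICES):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    cols = center_rc[1] + semi_col * np.cos(t)
    rows = center_rc[0] + semi_row * np.sin(t)
    return np.stack([rows, cols], axis=1)


def _poly_xy(rc_polygon) -> ShapelyPolygon:
    """Shapely polygon in (x=col, y=row) space from an (row, col) array."""
    rc = np.asarray(rc_polygon, dtype=float)
    return ShapelyPolygon(rc[:, ::-1])


def _sample_points(rng, n, region: ShapelyPolygon, n_candidates=24):
    """Mitchell's best-candidate sampling: well-separated points in *region*."""
    minx, miny, maxx, maxy = region.bounds
    pts = []
    while len(pts) < n:
        best, best_d = None, -1.0
        tries = 0
        while tries < n_candidates:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if not region.contains(Point(x, y)):
                continue
            tries += 1
            d = min((np.hypot(x - px, y - py) for px, py in pts), default=np.inf)
            if d > best_d:
                best, best_d = (x, y), d
        pts.append(best)
    return np.array(pts)  # (n, 2) in (x, y) = (col, row)


def make_wing(n_cells: int = 10, vein_width: int = DEFAULT_VEIN_WIDTH,
              size=DEFAULT_SIZE, seed: int = 0, max_tries: int = 40,
              min_cell_area: float = MIN_CELL_AREA,
              min_junction_sep: float = MIN_JUNCTION_SEP) -> WingFixture:
    """Generate a wing fixture with *n_cells* Voronoi cells.

    Candidate tessellations violating the validity constraints (cells big
    enough to survive the stroke width, junctions separated enough to be
    individually resolvable) are resampled from the same random stream; a
    :class:`GenerationError` suggests a larger image when *max_tries*
    candidates all fail.
    """
    if n_cells < 1 or vein_width < 1:
        raise GenerationError("n_cells and vein_width must be >= 1")
    h, w = size
    rng = np.random.default_rng(seed)
    centre = (h / 2.0, w / 2.0)
    outline_rc = _ellipse(centre, 0.36 * h, 0.44 * w)
    outline = _poly_xy(outline_rc)
    seed_region = _poly_xy(_ellipse(centre, 0.30 * h, 0.38 * w))

    last_err = "no candidate generated"
    for _ in range(max_tries):
        pts = _sample_points(rng, n_cells, seed_region)
        try:
            cells, junctions, vein_lines = _tessellate(
                pts, outline, vein_width, min_cell_area, min_junction_sep)
        except GenerationError as err:
            last_err = str(err)
            continue
        image = _render(outline, vein_lines, vein_width, size)
        return WingFixture(
            image=image, silhouette=outline_rc, cells=cells,
            junctions=junctions, seed=seed,
            params={"n_cells": n_cells, "vein_width": vein_width,
                    "size": tuple(size)},
            vein_lines=vein_lines)
    raise GenerationError(
        f"could not fit {n_cells} cells of >= {min_cell_area} px^2 in a "
        f"{size} image after {max_tries} tries ({last_err}); "
        "try a larger image or fewer cells")


def _tessellate(pts, outline, vein_width, min_cell_area, min_junction_sep):
    """Clip the Voronoi diagram of *pts* to the outline; returns truth cell
    polygons (row, col), junctions and the vein centreline geometry."""
    n_cells = len(pts)
    if n_cells == 1:
        ring = LineString(np.asarray(outline.exterior.coords))
        truth = outline.buffer(-(vein_width - 1) / 2.0)
        return ([np.asarray(truth.exterior.coords)[:, ::-1]],
                np.empty((0, 2)), ring)

    span = 6.0 * max(outline.bounds[2], outline.bounds[3])
    cx, cy = outline.centroid.x, outline.centroid.y
    t = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    dummies = np.stack([cx + span * np.cos(t), cy + span * np.sin(t)], axis=1)
    vor = Voronoi(np.vstack([pts, dummies]))

    erode = (vein_width - 1) / 2.0
    cells = []
    for i in range(n_cells):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise GenerationError("unbounded Voronoi cell")
        poly = ShapelyPolygon(vor.vertices[region]).intersection(outline)
        truth = poly.buffer(-erode) if not poly.is_empty else poly
        if truth.is_empty or truth.geom_type != "Polygon":
            raise GenerationError("cell vanishes under the stroke width")
        if truth.area < min_cell_area:
            raise GenerationError("cell below the minimum area")
        cells.append(np.asarray(truth.exterior.coords)[:, ::-1])

    # ridge segments between real cells, clipped to the outline
    segments = []
    for (p, q), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n_cells and q >= n_cells:
            continue
        if -1 in ridge:
            continue
        seg = LineString(vor.vertices[ridge]).intersection(outline)
        if not seg.is_empty and seg.length > 0:
            segments.append(seg)
    vein_lines = unary_union(
        segments + [LineString(np.asarray(outline.exterior.coords))])

    junctions_xy = []
    for v in vor.vertices:
        if outline.contains(Point(v)):
            junctions_xy.append(v)
    # ridge-outline crossings: clipped-segment endpoints landing on the ring
    boundary_ring = LineString(np.asarray(outline.exterior.coords))
    for seg in segments:
        for part in getattr(seg, "geoms", [seg]):
            for xy in (part.coords[0], part.coords[-1]):
                if boundary_ring.distance(Point(xy)) < 1e-6:
                    junctions_xy.append(list(xy))
    junctions_xy = np.array(junctions_xy) if junctions_xy else np.empty((0, 2))
    if len(junctions_xy) > 1:
        d = cdist(junctions_xy, junctions_xy)
        np.fill_diagonal(d, np.inf)
        if d.min() < min_junction_sep:
            raise GenerationError("junctions too close to resolve individually")
    return cells, junctions_xy[:, ::-1], vein_lines  # junctions to (row, col)


def _render(outline, vein_lines, vein_width, size) -> np.ndarray:
    """Binary rendering: a pixel is black iff its centre lies within half a
    stroke width of a vein centreline (inside-outline strokes plus the
    outline ring itself)."""
    h, w = size
    stroke = vein_lines.buffer(vein_width / 2.0, cap_style="round")
    cc, rr = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    black = shapely.contains_xy(stroke, cc.ravel(), rr.ravel()).reshape(h, w)
    return ~black


def make_damaged(fixture: WingFixture, hole_spec) -> WingFixture:
    """Cut holes into a fixture.

    *hole_spec* is a list of ``((row, col), radius)`` circles or (k, 2)
    polygon arrays, each strictly inside the silhouette.  Pixels inside a
    hole become white and the torn rim is drawn as a stroke; truth cells are
    trimmed (parts below the minimum area are dropped) and hole polygons
    recorded.  An empty spec returns the fixture unchanged.
    """
    if not hole_spec:
        return fixture
    vein_width = fixture.params["vein_width"]
    size = fixture.params["size"]
    outline = _poly_xy(fixture.silhouette)
    erode = (vein_width - 1) / 2.0

    holes_xy = []
    for spec in hole_spec:
        if isinstance(spec, tuple) and len(spec) == 2 and np.isscalar(spec[1]):
            (r, c), radius = spec
            poly = Point(c, r).buffer(radius, quad_segs=32)
        else:
            poly = _poly_xy(np.asarray(spec))
        if not outline.buffer(-vein_width).contains(poly):
            raise GenerationError("hole must lie strictly inside the silhouette")
        holes_xy.append(poly)

    hole_union = unary_union(holes_xy)
    rim = unary_union([p.exterior for p in holes_xy])
    vein_lines = fixture.vein_lines.difference(hole_union.buffer(vein_width))
    vein_lines = unary_union([vein_lines, rim])
    image = _render(outline, vein_lines, vein_width, size)

    cells = []
    for cell in fixture.cells:
        trimmed = _poly_xy(cell).difference(hole_union.buffer(erode))
        parts = getattr(trimmed, "geoms", [trimmed])
        for part in parts:
            if part.geom_type == "Polygon" and part.area >= MIN_CELL_AREA:
                cells.append(np.asarray(part.exterior.coords)[:, ::-1])

    keep = []
    for j in fixture.junctions:
        if not hole_union.buffer(vein_width).contains(Point(j[1], j[0])):
            keep.append(j)
    new_j = []
    inter = rim.intersection(fixture.vein_lines)  # transversal rim crossings
    for geom in getattr(inter, "geoms", [inter] if not inter.is_empty else []):
        if geom.geom_type == "Point":
            new_j.append([geom.y, geom.x])
    junctions = np.array(keep + new_j) if keep or new_j else np.empty((0, 2))

    truth_holes = [np.asarray(p.buffer(-erode).exterior.coords)[:, ::-1]
                   for p in holes_xy]
    return WingFixture(image=image, silhouette=fixture.silhouette, cells=cells,
                       junctions=junctions, seed=fixture.seed,
                       params=dict(fixture.params), holes=truth_holes,
                       secondary=fixture.secondary, vein_lines=vein_lines)


def make_secondary(size, profile) -> np.ndarray:
    """Render an analytic height profile ``h(x, y) in [0, 1]`` as a secondary
    corrugation image: ``intensity = 255 * (1 - h)`` (white valleys, black
    hills), rounded to uint8."""
    h, w = size
    cc, rr = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    z = np.asarray(profile(cc, rr), dtype=float)
    if z.shape != (h, w):
        raise GenerationError(f"profile returned shape {z.shape}, expected {(h, w)}")
    if z.min() < -1e-9 or z.max() > 1 + 1e-9:
        raise GenerationError("profile must map into [0, 1]")
    return np.clip(np.round(255.0 * (1.0 - z)), 0, 255).astype(np.uint8)


def match_points(detected, truth, tol: float = 3.0):
    """One-to-one matching of detected points to ground truth within *tol*
    (Hungarian assignment).  Returns ``(n_matched, n_detected, n_truth)``."""
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(detected) == 0 or len(truth) == 0:
        return 0, len(detected), len(truth)
    d = cdist(detected, truth)
    cost = np.minimum(d, 2 * tol)
    ri, ci = linear_sum_assignment(cost)
    matched = int(np.sum(d[ri, ci] <= tol))
    return matched, len(detected), len(truth)


def write_fixture(fixture: WingFixture, out_dir, stem: str = "wing"):
    """Write the fixture as PNG(s) plus a ground-truth JSON bundle."""
    from pathlib import Path

    from .imaging import save_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_image(fixture.image, out / f"{stem}.png")
    if fixture.secondary is not None:
        save_image(fixture.secondary, out / f"{stem}_secondary.png")
    truth = {
        "seed": fixture.seed,
        "params": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in fixture.params.items()},
        "silhouette": fixture.silhouette.tolist(),
        "cells": [c.tolist() for c in fixture.cells],
        "holes": [h.tolist() for h in fixture.holes],
        "junctions": fixture.junctions.tolist(),
    }
    with open(out / f"{stem}_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
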