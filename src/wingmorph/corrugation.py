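"""Corrugation assignment from a secondary grayscale image.

Insect wings are not flat: pleats (corrugation) and camber strongly affect
their stiffness.  The out-of-plane shape is supplied as a *secondary* image
of the same size as the wing image, in which pixel intensity encodes height:
white lies in the valleys (z = 0) and black on the hills (z = peak), linearly
in between.

The secondary image is subdivided into ``n_sections`` equally spaced vertical
section lines.  Along each section the intensity profile is converted to a
height curve and smoothed with a 1-D Gaussian whose width varies inversely
with the ``sharpness`` knob (a soft greyish fade next to each height maximum
avoids physically implausible height jumps).  Between sections, heights are
interpolated linearly along the horizontal axis — the linear loft path — and
the lofted sheet is trimmed to the wing outline, giving the corrugated shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import Point, Polygon as ShapelyPolygon

from .errors import DegenerateInputError

#: Gaussian smoothing constant: sigma = SMOOTHING_K / sharpness (px).
SMOOTHING_K = 4.0

#: Half-width of the column band averaged at each section line (px).
SECTION_BAND_HALFWIDTH = 1


@dataclass
class CorrugationParams:
    """Knobs of the corrugation model.

    ``peak_height`` and ``sharpness`` may be scalars (applied to every
    section, mirroring linked-section editing) or per-section sequences of
    length ``n_sections`` (independent sections).
    """

    n_sections: int = 10
    peak_height: float | np.ndarray = 10.0
    sharpness: float | np.ndarray = 1.0
    link_sections: bool = True

    def __post_init__(self):
        if self.n_sections < 2:
            raise DegenerateInputError("a loft needs at least two sections")
        if np.any(np.asarray(self.peak_height, dtype=float) < 0):
            raise DegenerateInputError("peak_height must be >= 0")
        if np.any(np.asarray(self.sharpness, dtype=float) <= 0):
            raise DegenerateInputError("sharpness must be > 0")

    def per_section(self, value) -> np.ndarray:
        out = np.broadcast_to(np.asarray(value, dtype=float),
                              (self.n_sections,)).copy()
        return out


@dataclass
class HeightField:
    """Sampled height curves z(row) at fixed column positions."""

    sections: np.ndarray          # (n_sections, height)
    section_positions: np.ndarray  # (n_sections,) strictly increasing columns
    peaks: np.ndarray             # (n_sections,) per-section peak height


@dataclass
class CorrugatedSurface:
    vertices: np.ndarray   # (n, 3) float: x, y, z (Cartesian, y up)
    faces: np.ndarray      # (m, 3) int triangles
    trimmed: bool = True
    source_field: "HeightField | None" = None  # sections that built the loft


def height_from_intensity(v, peak: float):
    """Map intensity to height: ``z = peak * (1 - v / 255)``.

    White (255) lies in the valleys (z = 0), black (0) on the hills
    (z = peak).
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0) or np.any(v > 255):
        raise DegenerateInputError("intensity outside [0, 255]")
    return peak * (1.0 - v / 255.0)


def extract_sections(secondary: np.ndarray, params: CorrugationParams,
                     expected_shape=None) -> HeightField:
    """Sample smoothed height curves along equally spaced vertical sections.

    At each section line a band of ``2 * SECTION_BAND_HALFWIDTH + 1`` columns
    is averaged (noise resistance), mapped to heights, then smoothed with a
    Gaussian of ``sigma = SMOOTHING_K / sharpness``.
    """
    secondary = np.asarray(secondary, dtype=float)
    if secondary.ndim != 2:
        raise DegenerateInputError("secondary image must be 2-D grayscale")
    if expected_shape is not None and secondary.shape != tuple(expected_shape):
        raise DegenerateInputError(
            f"secondary image {secondary.shape} does not match wing image "
            f"{tuple(expected_shape)}"
        )
    h, w = secondary.shape
    positions = np.round(np.linspace(0, w - 1, params.n_sections)).astype(int)
    if len(np.unique(positions)) != params.n_sections:
        raise DegenerateInputError(
            f"image of width {w} cannot host {params.n_sections} distinct sections"
        )
    peaks = params.per_section(params.peak_height)
    sharps = params.per_section(params.sharpness)
    sections = np.empty((params.n_sections, h))
    for i, (pos, peak, sharp) in enumerate(zip(positions, peaks, sharps)):
        lo = max(0, pos - SECTION_BAND_HALFWIDTH)
        hi = min(w, pos + SECTION_BAND_HALFWIDTH + 1)
        profile = secondary[:, lo:hi].mean(axis=1)
        z = height_from_intensity(profile, peak)
        z = gaussian_filter1d(z, sigma=SMOOTHING_K / sharp, mode="nearest")
        sections[i] = np.clip(z, 0.0, peak if peak > 0 else 0.0)
    return HeightField(sections=sections,
                       section_positions=positions.astype(float), peaks=peaks)


def interpolate_height(field: HeightField, cols) -> np.ndarray:
    """Height surface z(row, col) for the given columns: linear interpolation
    between adjacent section curves along the horizontal axis (the linear
    loft path).  Returns an array of shape ``(height, len(cols))``."""
    cols = np.asarray(cols, dtype=float)
    pos = field.section_positions
    n, h = field.sections.shape
    idx = np.clip(np.searchsorted(pos, cols, side="right") - 1, 0, n - 2)
    x0, x1 = pos[idx], pos[idx + 1]
    t = np.clip((cols - x0) / (x1 - x0), 0.0, 1.0)
    return (1 - t)[None, :] * field.sections[idx].T + t[None, :] * field.sections[idx + 1].T


def loft_surface(field: HeightField, boundary, holes=(),
                 image_height: int | None = None,
                 grid_step: int = 1) -> CorrugatedSurface:
    """Loft the section curves into a triangulated surface trimmed to the
    wing outline.

    *boundary* and each entry of *holes* are (k, 2) ``(row, col)`` polygon
    vertex arrays (e.g. simplified boundaries).  The surface is sampled on a
    regular pixel grid at *grid_step*, keeping grid cells whose four corners
    fall inside the outline and outside every hole; each kept quad is split
    into two triangles.  Output coordinates are Cartesian (y up) with
    ``image_height`` (default: derived from the field) setting the flip.
    """
    boundary = np.asarray(boundary, dtype=float)
    if len(boundary) < 3:
        raise DegenerateInputError("outline polygon needs >= 3 vertices")
    n, h = field.sections.shape
    if image_height is None:
        image_height = h
    poly = ShapelyPolygon(boundary[:, ::-1],
                          [np.asarray(hole, dtype=float)[:, ::-1] for hole in holes])
    # grid in (col, row) space covering the outline
    rmin = max(0, int(np.floor(boundary[:, 0].min())))
    rmax = min(h - 1, int(np.ceil(boundary[:, 0].max())))
    cmin = int(np.floor(boundary[:, 1].min()))
    cmax = int(np.ceil(boundary[:, 1].max()))
    rows = np.arange(rmin, rmax + 1, grid_step)
    cols = np.arange(cmin, cmax + 1, grid_step)
    if len(rows) < 2 or len(cols) < 2:
        raise DegenerateInputError("outline does not overlap the height grid")
    cc, rr = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(poly, cc.ravel(), rr.ravel()).reshape(rr.shape)
    if not inside.any():
        raise DegenerateInputError("outline encloses no grid point")

    z_cols = interpolate_height(field, cols)  # (h, len(cols)): all image rows
    z = z_cols[rows, :]

    # keep quads by centre so boundary area errors cancel instead of biasing
    # the mesh small; outside corner vertices are snapped onto the boundary
    # afterwards so every vertex lies inside or on the outline.
    centre_c = (cc[:-1, :-1] + cc[1:, 1:]) / 2.0
    centre_r = (rr[:-1, :-1] + rr[1:, 1:]) / 2.0
    quad = shapely.contains_xy(poly, centre_c.ravel(),
                               centre_r.ravel()).reshape(centre_c.shape)

    vid = -np.ones(inside.shape, dtype=np.int64)
    used = np.zeros_like(inside)
    used[:-1, :-1] |= quad
    used[:-1, 1:] |= quad
    used[1:, :-1] |= quad
    used[1:, 1:] |= quad
    pts = np.argwhere(used)
    vid[pts[:, 0], pts[:, 1]] = np.arange(len(pts))
    x = cc[pts[:, 0], pts[:, 1]].astype(float)
    row_px = rr[pts[:, 0], pts[:, 1]].astype(float)
    outside = ~inside[pts[:, 0], pts[:, 1]]
    if outside.any():
        ring = poly.boundary
        for k in np.flatnonzero(outside):
            snapped = ring.interpolate(ring.project(Point(x[k], row_px[k])))
            x[k], row_px[k] = snapped.x, snapped.y
    y = (image_height - 1) - row_px
    zz = z[pts[:, 0], pts[:, 1]]
    vertices = np.stack([x, y, zz], axis=1)
    qr, qc = np.where(quad)
    a = vid[qr, qc]
    b = vid[qr, qc + 1]
    c = vid[qr + 1, qc + 1]
    d = vid[qr + 1, qc]
    faces = np.concatenate([np.stack([a, b, c], axis=1),
                            np.stack([a, c, d], axis=1)])
    if len(faces) == 0:
        raise DegenerateInputError("outline too thin to mesh at this grid step")
    return CorrugatedSurface(vertices=vertices, faces=faces, trimmed=True,
                             source_field=field)
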