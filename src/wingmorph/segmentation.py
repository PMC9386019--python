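"""Region extraction from a binarised wing image.

The extraction follows an iterative flood ("burning") scheme: starting from a
white seed pixel, the frontier grows in the four cardinal directions through
white pixels, while every black pixel touching the frontier in any of the
eight directions is recorded as region boundary.  The connectivity asymmetry
is deliberate and is what makes the method work on venation images:

* white growth is 4-connected, so two cells separated by a single-pixel
  diagonal vein line never merge (no percolation through diagonal gaps);
* black capture is 8-connected, so the recorded boundary ring is closed even
  across diagonal steps of the vein.

Visited pixels are tracked in an explicit label grid (equivalent to the
classic trick of recolouring found pixels grey, but non-destructive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import InvalidSeedError, NoWingFoundError, TracingError

# 4- and 8-neighbour offsets in (row, col).
CARDINALS = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)])
ALL_EIGHT = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)

#: Regions smaller than this many white pixels are discarded as noise.
DEFAULT_MIN_AREA = 4


@dataclass
class DomainRegion:
    """A detected region: the wing silhouette, one cell, or one hole.

    ``interior`` holds the region's own pixels, ``boundary_pixels`` the black
    pixels 8-adjacent to them, and ``boundary_chain`` an ordered cyclic Moore
    contour.  All coordinates are ``(row, col)`` pairs.
    """

    kind: str  # 'main' | 'subdomain' | 'discontinuity'
    id: int
    interior: np.ndarray       # (n, 2) int
    boundary_pixels: np.ndarray  # (m, 2) int
    boundary_chain: np.ndarray   # (k, 2) int, ordered, cyclic (no repeated endpoint)

    @property
    def area(self) -> int:
        return len(self.interior)

    @property
    def bbox(self):
        """(row_min, col_min, row_max, col_max) of the interior."""
        mn = self.interior.min(axis=0)
        mx = self.interior.max(axis=0)
        return (int(mn[0]), int(mn[1]), int(mx[0]), int(mx[1]))

    def interior_mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.interior[:, 0], self.interior[:, 1]] = True
        return m


@dataclass
class SegmentationResult:
    """Main wing silhouette plus its cells and holes."""

    main: DomainRegion
    subdomains: list = field(default_factory=list)
    discontinuities: list = field(default_factory=list)
    shape: tuple = (0, 0)

    @property
    def regions(self):
        return [self.main, *self.subdomains, *self.discontinuities]

    def region_by_id(self, region_id: int) -> DomainRegion:
        for r in self.regions:
            if r.id == region_id:
                return r
        raise KeyError(f"no region with id {region_id}")


def flood_domain(img: np.ndarray, seed, label: np.ndarray | None = None,
                 region_id: int = 0, kind: str = "subdomain",
                 trace: bool = True) -> DomainRegion:
    """Flood the white region containing *seed*.

    Wave-by-wave frontier expansion: each iteration advances one step in the
    four cardinal directions through unvisited white pixels; black pixels
    seen in any of the eight directions are captured as boundary.  Terminates
    when no undetected white pixel remains in the region.

    *label*, when given, is a shared int grid: visited interior pixels are
    stamped with ``region_id`` (callers use it to skip already-extracted
    regions); it must be 0 where unvisited.
    """
    img = np.asarray(img, dtype=bool)
    seed = (int(seed[0]), int(seed[1]))
    h, w = img.shape
    if not (0 <= seed[0] < h and 0 <= seed[1] < w):
        raise InvalidSeedError(f"seed {seed} outside image {img.shape}")
    if not img[seed]:
        raise InvalidSeedError(f"seed {seed} is black; flood requires a white seed")

    visited = np.zeros(img.shape, dtype=bool)
    visited[seed] = True
    frontier = np.array([seed], dtype=np.int64)
    while frontier.size:
        cand = (frontier[:, None, :] + CARDINALS[None, :, :]).reshape(-1, 2)
        ok = (
            (cand[:, 0] >= 0) & (cand[:, 0] < h)
            & (cand[:, 1] >= 0) & (cand[:, 1] < w)
        )
        cand = cand[ok]
        flat = cand[:, 0] * w + cand[:, 1]
        flat = np.unique(flat)
        rr, cc = flat // w, flat % w
        new = img[rr, cc] & ~visited[rr, cc]
        rr, cc = rr[new], cc[new]
        visited[rr, cc] = True
        frontier = np.stack([rr, cc], axis=1)

    interior_mask = visited
    # black pixels 8-adjacent to the interior
    ring = ndimage.binary_dilation(interior_mask, structure=np.ones((3, 3), bool))
    boundary_mask = ring & ~img
    interior = np.argwhere(interior_mask)
    boundary = np.argwhere(boundary_mask)

    if label is not None:
        label[interior_mask] = region_id

    chain = _chain_for_region(interior_mask, boundary_mask) if trace else np.empty((0, 2), int)
    return DomainRegion(kind=kind, id=region_id, interior=interior,
                        boundary_pixels=boundary, boundary_chain=chain)


def _chain_for_region(interior_mask, boundary_mask) -> np.ndarray:
    """Closed contour of a region: trace the boundary ring when it is a single
    8-connected set, otherwise fall back to the outer contour of the filled
    region (regions truncated by the image border have an open ring)."""
    boundary = np.argwhere(boundary_mask)
    if len(boundary):
        try:
            return trace_boundary(boundary)
        except TracingError:
            pass
    return moore_trace(interior_mask | boundary_mask)


def detect_main_domain(img: np.ndarray) -> DomainRegion:
    """Detect the wing silhouette: everything not in the border-connected
    white background.  The silhouette includes both vein (black) and cell
    (white) pixels; its contour traces the outer side of the wing outline."""
    img = np.asarray(img, dtype=bool)
    h, w = img.shape
    if img.all():
        raise NoWingFoundError("image is entirely white: no wing structure")
    if not img.any():
        raise NoWingFoundError("image is entirely black: no background contrast")

    background = _border_flood(img)
    main_mask = ~background
    if not main_mask.any():
        raise NoWingFoundError("no structure detected inside the background")
    # keep only the largest connected silhouette (stray specks are not the wing)
    lab, n = ndimage.label(main_mask, structure=np.ones((3, 3)))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        main_mask = lab == (1 + int(np.argmax(sizes)))

    outside = ~main_mask
    ring = ndimage.binary_dilation(outside, structure=np.ones((3, 3), bool))
    ring[0, :] = ring[-1, :] = ring[:, 0] = ring[:, -1] = True
    boundary_mask = main_mask & ring & ~img  # black silhouette pixels facing outwards
    chain = moore_trace(main_mask)
    return DomainRegion(kind="main", id=0,
                        interior=np.argwhere(main_mask),
                        boundary_pixels=np.argwhere(boundary_mask),
                        boundary_chain=chain)


def _border_flood(img: np.ndarray) -> np.ndarray:
    """White pixels 4-connected to the image border (the background)."""
    h, w = img.shape
    lab, _ = ndimage.label(img, structure=ndimage.generate_binary_structure(2, 1))
    border_labels = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    border_labels = border_labels[border_labels != 0]
    return np.isin(lab, border_labels)


def detect_subdomains(img: np.ndarray, main: DomainRegion,
                      min_area: int = DEFAULT_MIN_AREA) -> list:
    """Extract every enclosed white region (wing cell candidate) inside the
    silhouette by repeated flooding from unvisited white seeds, in scan order.
    Regions with fewer than *min_area* pixels are discarded as noise."""
    img = np.asarray(img, dtype=bool)
    main_mask = main.interior_mask(img.shape)
    label = np.zeros(img.shape, dtype=np.int32)
    regions = []
    next_id = 1
    candidates = np.argwhere(img & main_mask)
    for seed in candidates:
        if label[seed[0], seed[1]]:
            continue
        region = flood_domain(img, seed, label=label, region_id=next_id,
                              kind="subdomain")
        if region.area < min_area:
            continue
        regions.append(region)
        next_id += 1
    return regions


def segment(img: np.ndarray, min_area: int = DEFAULT_MIN_AREA,
            hole_seeds=()) -> SegmentationResult:
    """Full segmentation: main silhouette, cells, and (optionally) holes
    reclassified from the given seed pixels."""
    main = detect_main_domain(img)
    subs = detect_subdomains(img, main, min_area=min_area)
    result = SegmentationResult(main=main, subdomains=subs,
                                discontinuities=[], shape=img.shape)
    if len(hole_seeds):
        result = mark_discontinuities(result, hole_seeds)
    return result


def mark_discontinuities(result: SegmentationResult, seeds) -> SegmentationResult:
    """Reclassify the cell containing each seed as a hole (discontinuity).

    Holes are pixel-wise indistinguishable from cells, so they are declared
    by the user; reclassified regions are excluded from cell morphometrics
    and cut out of exported geometry.
    """
    for seed in seeds:
        seed = (int(seed[0]), int(seed[1]))
        hit = None
        for region in result.subdomains:
            mask_hit = np.any(
                (region.interior[:, 0] == seed[0]) & (region.interior[:, 1] == seed[1])
            )
            if mask_hit:
                hit = region
                break
        if hit is None:
            raise InvalidSeedError(f"seed {seed} lies in no detected subdomain")
        hit.kind = "discontinuity"
        result.subdomains.remove(hit)
        result.discontinuities.append(hit)
    return result


# ---------------------------------------------------------------------------
# Moore-neighbour contour tracing
# ---------------------------------------------------------------------------

# clockwise Moore neighbourhood starting east, in (row, col)
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def moore_trace(mask: np.ndarray) -> np.ndarray:
    """Outer contour of the foreground in *mask* by Moore-neighbour tracing.

    Starts at the lexicographically smallest foreground pixel and walks
    clockwise; terminates by Jacob's criterion (re-entering the start pixel
    from the starting direction).  Returns an ordered cyclic chain whose
    consecutive members are 8-adjacent.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if len(pts) == 0:
        raise TracingError("empty pixel set")
    start = tuple(pts[np.lexsort((pts[:, 1], pts[:, 0]))[0]])
    if len(pts) == 1:
        return np.array([start])

    h, w = mask.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    def step(cur, prev):
        """Next contour pixel scanning clockwise from the backtrack *prev*."""
        base = _MOORE.index((prev[0] - cur[0], prev[1] - cur[1]))
        for k in range(1, 9):
            d = _MOORE[(base + k) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if fg(cand):
                back = (cur[0] + _MOORE[(base + k - 1) % 8][0],
                        cur[1] + _MOORE[(base + k - 1) % 8][1])
                return cand, back
        return None, None

    # backtrack: west of start (background, since start is the lexicographic
    # minimum of its row and the row above is empty)
    chain = []
    cur, prev = start, (start[0], start[1] - 1)
    first_move = None
    guard = 8 * len(pts) + 16
    while guard:
        guard -= 1
        nxt, back = step(cur, prev)
        if nxt is None:  # isolated start pixel
            return np.array([start])
        if cur == start:
            if first_move is None:
                first_move = nxt
            elif nxt == first_move:  # Jacob's criterion: leaving start the same way
                break
        chain.append(cur)
        cur, prev = nxt, back
    return np.array(chain)


def trace_boundary(boundary_pixels) -> np.ndarray:
    """Order a closed 8-connected boundary ring into a cyclic chain.

    Raises :class:`TracingError` (carrying the component breakdown) when the
    pixels do not form a single 8-connected set.
    """
    pts = np.asarray(boundary_pixels)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise TracingError("boundary pixel set is empty or malformed")
    mn = pts.min(axis=0)
    local = pts - mn + 1
    shape = (local[:, 0].max() + 2, local[:, 1].max() + 2)
    mask = np.zeros(shape, dtype=bool)
    mask[local[:, 0], local[:, 1]] = True
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n != 1:
        comps = [np.argwhere(lab == i) + mn - 1 for i in range(1, n + 1)]
        raise TracingError(
            f"boundary pixels form {n} disconnected components", components=comps
        )
    chain = moore_trace(mask)
    return chain + mn - 1


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def result_to_dict(result: SegmentationResult) -> dict:
    def region_dict(r):
        return {
            "kind": r.kind,
            "id": r.id,
            "area": r.area,
            "bbox": list(r.bbox),
            "boundary_chain": r.boundary_chain.tolist(),
        }

    return {
        "shape": list(result.shape),
        "main": region_dict(result.main),
        "subdomains": [region_dict(r) for r in result.subdomains],
        "discontinuities": [region_dict(r) for r in result.discontinuities],
    }


def write_result_json(result: SegmentationResult, path, extra: dict | None = None):
    doc = result_to_dict(result)
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_label_map(result: SegmentationResult, path):
    """Write the region label map as an indexed (palette) PNG: 0 background,
    1 main silhouette, ids+1 for cells and holes."""
    lab = np.zeros(result.shape, dtype=np.uint8)
    lab[result.main.interior[:, 0], result.main.interior[:, 1]] = 1
    for r in [*result.subdomains, *result.discontinuities]:
        lab[r.interior[:, 0], r.interior[:, 1]] = (r.id + 1) % 256
    im = Image.fromarray(lab, mode="P")
    rng = np.random.default_rng(0)
    palette = rng.integers(40, 255, size=(256, 3), dtype=np.uint8)
    palette[0] = (0, 0, 0)
    palette[1] = (60, 60, 60)
    im.putpalette(palette.flatten().tolist())
    im.save(path)
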