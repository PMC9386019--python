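"""Vein skeletonisation and junction detection.

Vein junctions (where two or more veins intersect) are found in two steps:
the dark vein network is thinned to one-pixel-wide centrelines with the
two-subiteration Zhang-Suen algorithm, then every skeleton pixel whose
8-neighbourhood shows three or more branches is flagged.  Branch count is
the number of black-to-white transitions A(P1) in the cyclic neighbour walk
P2..P9,P2 (P2 = north, clockwise); the classic junction pattern — cardinal
neighbours white, diagonals black — has four transitions and is one case of
this criterion.

Adjacent junction pixels at a single physical crossing are collapsed by
single-linkage clustering into one representative junction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

DEFAULT_MERGE_RADIUS = 3.0


@dataclass
class JunctionSet:
    """Merged junctions plus the raw junction pixels they came from."""

    junctions: np.ndarray                      # (k, 2) int, cluster representatives
    raw_pixels: np.ndarray                     # (m, 2) int
    merge_radius: float = DEFAULT_MERGE_RADIUS
    clusters: list = field(default_factory=list)  # per-junction member index lists

    def __len__(self):
        return len(self.junctions)


def _neighbours(padded):
    """The eight neighbour planes of a zero-padded boolean image, ordered
    P2..P9 (N, NE, E, SE, S, SW, W, NW)."""
    c = padded[1:-1, 1:-1]
    return [
        padded[:-2, 1:-1],   # P2 N
        padded[:-2, 2:],     # P3 NE
        padded[1:-1, 2:],    # P4 E
        padded[2:, 2:],      # P5 SE
        padded[2:, 1:-1],    # P6 S
        padded[2:, :-2],     # P7 SW
        padded[1:-1, :-2],   # P8 W
        padded[:-2, :-2],    # P9 NW
    ], c


def _transitions(nb):
    """A(P1): 0->1 transitions in the cyclic sequence P2..P9,P2."""
    a = np.zeros(nb[0].shape, dtype=np.uint8)
    for i in range(8):
        a += (~nb[i] & nb[(i + 1) % 8]).astype(np.uint8)
    return a


def zhang_suen_thin(veins: np.ndarray, prune_blocks: bool = True) -> np.ndarray:
    """Thin white strokes to one-pixel centrelines (Zhang-Suen).

    Two subiterations per pass; a white pixel is deleted iff
    2 <= B(P1) <= 6, A(P1) = 1 and the subiteration's two cardinal products
    vanish (pass 1: P2*P4*P6 = 0 and P4*P6*P8 = 0; pass 2: P2*P4*P8 = 0 and
    P2*P6*P8 = 0).  Runs until no pixel changes.  Borders are treated as
    black via padding.

    The parallel passes have a known fixpoint artifact: at X-crossings they
    can leave a 2x2 block whose pixels all have transition count 2 (so the
    A = 1 rule never fires) even though some are 8-simple.  With
    *prune_blocks* (default) a sequential cleanup deletes 8-simple pixels of
    residual 2x2 blocks, preserving topology, so the result satisfies the
    one-pixel-wide contract.
    """
    img = np.asarray(veins, dtype=bool).copy()
    if img.size == 0 or not img.any():
        return img
    while True:
        changed = False
        for phase in (0, 1):
            padded = np.pad(img, 1, constant_values=False)
            nb, centre = _neighbours(padded)
            b = np.zeros(img.shape, dtype=np.uint8)
            for plane in nb:
                b += plane.astype(np.uint8)
            a = _transitions(nb)
            p2, p4, p6, p8 = nb[0], nb[2], nb[4], nb[6]
            if phase == 0:
                cond = ~(p2 & p4 & p6) & ~(p4 & p6 & p8)
            else:
                cond = ~(p2 & p4 & p8) & ~(p2 & p6 & p8)
            delete = img & (b >= 2) & (b <= 6) & (a == 1) & cond
            if delete.any():
                _guard_vanishing(img, delete)
            if delete.any():
                img[delete] = False
                changed = True
        if not changed:
            break
    if prune_blocks:
        _prune_redundant_blocks(img)
    return img


def _guard_vanishing(img: np.ndarray, delete: np.ndarray) -> None:
    """Unset *delete* (in place) on one anchor pixel of any component the
    parallel subiteration would remove entirely.

    The parallel rule can delete every pixel of a small compact blob in one
    step (e.g. a bare 2x2 square), destroying a connected component; with
    this guard a blob thins to a single dot instead.
    """
    from scipy import ndimage

    lab, n = ndimage.label(img, structure=np.ones((3, 3)))
    if n == 0:
        return
    idx = np.arange(1, n + 1)
    total = ndimage.sum_labels(np.ones(img.shape), lab, index=idx)
    gone = ndimage.sum_labels(delete.astype(np.float64), lab, index=idx)
    for comp in idx[total == gone]:
        pts = np.argwhere(lab == comp)
        first = pts[np.lexsort((pts[:, 1], pts[:, 0]))[0]]
        delete[first[0], first[1]] = False


def _is_8_simple(patch: np.ndarray) -> bool:
    """Whether deleting the centre of a white 3x3 *patch* preserves local
    topology: its white neighbours form one 8-connected component and at
    least one cardinal neighbour is black (so no hole is created)."""
    from scipy import ndimage

    ring = patch.copy()
    ring[1, 1] = False
    n_fg = ring.sum()
    if n_fg == 0:
        return False
    if patch[0, 1] and patch[1, 0] and patch[1, 2] and patch[2, 1]:
        return False
    _, n = ndimage.label(ring, structure=np.ones((3, 3)))
    return n == 1


def _prune_redundant_blocks(img: np.ndarray) -> None:
    """Sequentially delete 8-simple pixels belonging to 2x2 white blocks
    (lexicographic order, repeated to a fixpoint).  In-place."""
    padded = np.pad(img, 1, constant_values=False)
    while True:
        blocks = (padded[:-1, :-1] & padded[:-1, 1:]
                  & padded[1:, :-1] & padded[1:, 1:])
        if not blocks.any():
            break
        changed = False
        for r, c in np.argwhere(blocks):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                pr, pc = r + dr, c + dc  # padded coords of a block member
                if not padded[pr, pc]:
                    continue
                if _is_8_simple(padded[pr - 1:pr + 2, pc - 1:pc + 2]):
                    padded[pr, pc] = False
                    changed = True
        if not changed:
            break
    img[:] = padded[1:-1, 1:-1]


def is_thin(skel: np.ndarray) -> bool:
    """True when the image contains no 2x2 all-white block."""
    s = np.asarray(skel, dtype=bool)
    return not (s[:-1, :-1] & s[:-1, 1:] & s[1:, :-1] & s[1:, 1:]).any()


def detect_junction_pixels(skel: np.ndarray) -> np.ndarray:
    """Junction pixels of a thin skeleton: white pixels with branch count
    (neighbour transitions) >= 3.  Warns but proceeds on non-thin input."""
    skel = np.asarray(skel, dtype=bool)
    if not is_thin(skel):
        warnings.warn("junction detection on a non-thin skeleton", stacklevel=2)
    padded = np.pad(skel, 1, constant_values=False)
    nb, _ = _neighbours(padded)
    a = _transitions(nb)
    return np.argwhere(skel & (a >= 3))


def merge_junction_clusters(raw, radius: float = DEFAULT_MERGE_RADIUS) -> JunctionSet:
    """Collapse raw junction pixels within *radius* (single linkage) into one
    junction at the rounded cluster centroid; ``radius = 0`` keeps every
    pixel as its own junction."""
    raw = np.asarray(raw, dtype=float).reshape(-1, 2)
    if len(raw) == 0:
        return JunctionSet(junctions=np.empty((0, 2), int),
                           raw_pixels=raw.astype(int), merge_radius=radius)
    if len(raw) == 1 or radius <= 0:
        members = [[i] for i in range(len(raw))]
    else:
        labels = fcluster(linkage(pdist(raw), method="single"),
                          t=radius, criterion="distance")
        members = [list(np.flatnonzero(labels == lab))
                   for lab in np.unique(labels)]
    reps = np.array(
        [np.rint(raw[m].mean(axis=0)).astype(int) for m in members]
    )
    order = np.lexsort((reps[:, 1], reps[:, 0]))
    return JunctionSet(junctions=reps[order], raw_pixels=raw.astype(int),
                       merge_radius=float(radius),
                       clusters=[members[i] for i in order])


def wing_vein_mask(binary_img: np.ndarray, main_interior_mask: np.ndarray | None = None
                   ) -> np.ndarray:
    """Foreground for thinning: the dark wing structure (outline + veins),
    i.e. black pixels restricted to the silhouette when a main-domain mask
    is given (background stays out even if dark)."""
    dark = ~np.asarray(binary_img, dtype=bool)
    if main_interior_mask is not None:
        dark = dark & np.asarray(main_interior_mask, dtype=bool)
    return dark


def find_junctions(binary_img: np.ndarray,
                   main_interior_mask: np.ndarray | None = None,
                   merge_radius: float = DEFAULT_MERGE_RADIUS):
    """Convenience pipeline: vein mask -> Zhang-Suen skeleton -> junction
    pixels -> merged junctions.  Returns ``(skeleton, JunctionSet)``."""
    veins = wing_vein_mask(binary_img, main_interior_mask)
    skel = zhang_suen_thin(veins)
    raw = detect_junction_pixels(skel)
    return skel, merge_junction_clusters(raw, radius=merge_radius)
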