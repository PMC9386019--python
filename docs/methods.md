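# Methods

This note records the models and algorithms `wingmorph` implements, the
parameters that matter, the design choices that were genuinely open, and
what the synthetic test conditions do and do not establish about real
images.

## Image model and conventions

The input is an 8-bit grayscale raster (colour converted by ITU-R 601
luminance, 16-bit TIFF rescaled) in which wing membranes photograph light
and veins dark. After thresholding, the package works on a boolean image
with **white = membrane foreground, black = vein/background**; images with
the opposite polarity must be inverted by the caller (`--invert`). Pixels
are addressed `(row, col)` with row 0 at the top; all geometry is exported
in Cartesian coordinates `x = col`, `y = height − 1 − row`.

Binarisation uses Otsu's between-class-variance threshold when none is
given; a constant image has no automatic threshold and is rejected. The
four input-suitability screens are advisory only (they warn, never block):
robust contrast span (2nd–98th percentile) below **80** levels → *faded*;
mean intensity below **60** → *dark*; more than **1 %** of pixels differing
from their 3×3 median by ≥ 100 levels → *salt-and-pepper*; median dark
stroke width below **2 px** → *thin lines* (stroke width estimated as
`2·EDT − 1` sampled on the stroke skeleton). The thresholds are package
defaults; nothing in the underlying method prescribes values, so they are
exposed as configuration.

## Region extraction

Regions are grown by an iterative flood with deliberately asymmetric
connectivity: the white frontier advances in the four cardinal directions
only, while black pixels in any of the eight surrounding directions are
captured as boundary. 4-connected white growth cannot percolate through a
one-pixel diagonal vein; 8-connected black capture still closes the
boundary ring across that diagonal. Visited pixels are tracked in an
explicit label grid (equivalent to recolouring found pixels grey, but
non-destructive). The flood is implemented wave-by-wave with vectorised
frontier expansion; it is pixel-for-pixel identical to 4-connected
component labelling (tested against `scipy.ndimage.label` as oracle).

The *main domain* (wing silhouette) is the complement of the white region
4-connected to the image border; if several dark structures survive, the
largest is taken. Enclosed white regions inside the silhouette become cell
candidates in scan order; regions under **4 px²** (configurable) are
discarded as noise. Holes are pixel-wise indistinguishable from cells, so
they are reclassified from user-supplied seed pixels, never guessed;
reclassified regions are excluded from cell statistics and cut from
exported geometry.

Boundary pixel sets are ordered by Moore-neighbour tracing (clockwise,
deterministic start at the lexicographically smallest pixel, Jacob's
stopping criterion). Regions truncated by the image border have an open
boundary ring; the tracer then falls back to the outer contour of the
filled region, which is the only case where the chain can contain
non-boundary pixels.

## Boundary simplification

Classic Ramer–Douglas–Peucker with perpendicular point-to-*segment*
distance: within each span the farthest point from the chord is kept iff
its distance exceeds ε, ties going to the smaller index so output is
deterministic. Closed chains are split at the lexicographically first
point and the point farthest from it, each half simplified open. This
yields the guarantee the tolerance names: every original point lies within
ε of the simplified polyline (directed Hausdorff bound), which the tests
assert on fuzzed chains. ε = 0 is special-cased to the identity —
a strict `> ε` recursion would still drop exactly collinear points.

*Arc accuracy* is reported as `100 · (1 − d_H / D)` clamped to [0, 100],
with `d_H` the directed Hausdorff distance from original points to the
simplified polyline and `D` the original chain's diameter. The metric name
is inherited from interactive wing-digitisation practice; no published
formula exists, so this scale-invariant normalisation is this package's own
definition. Default ε is **1 px**: morphometrics are computed on the
simplified boundary, and the induced area error is bounded by
`perimeter · ε` (asserted in tests).

## Morphometrics

For each cell polygon (simplified boundary, Cartesian): area is the
absolute shoelace sum `½|Σ xᵢyᵢ₊₁ − xᵢ₊₁yᵢ|`; length is the exact maximum
pairwise distance between boundary points (convex hull first, then all
hull pairs); width is defined as area/length; centroid is the standard
area-weighted polygon centroid. All four are translation- and
rotation-invariant and scale homogeneously; an optional scale (physical
length per pixel) converts lengths linearly and areas quadratically.
Histograms use equal-width bins over [min, max], right-open except the last
bin (NumPy convention).

## Skeleton and junctions

Vein centrelines come from the two-subiteration Zhang-Suen thinning of the
dark wing structure (background excluded): delete a white pixel iff
2 ≤ B ≤ 6, A = 1, and the subiteration's two cardinal products vanish,
iterated to a fixpoint, borders padded black. Two documented additions:

* **2×2 block pruning.** The parallel passes have fixpoints at X-crossings
  where a 2×2 block survives with every pixel at transition count 2, even
  though some are 8-simple. A sequential cleanup deletes 8-simple pixels of
  residual blocks (one 8-connected neighbour component, at least one black
  cardinal neighbour), preserving topology, so outputs satisfy the
  one-pixel-wide contract. Dense adversarial line tangles can still leave a
  block no single-pixel deletion can remove (≈1 % of random-crossing
  stress images; the scikit-image reference implementation leaves blocks in
  ≈30 % of the same images); clean venation networks are unaffected.
* **Vanishing guard.** The published parallel rule deletes a bare 2×2
  square — an entire component — in one step; a guard retains one anchor
  pixel so blobs thin to a dot. With both additions thinning preserves
  8-connected component count and hole count, verified against a
  brute-force topology oracle.

A skeleton pixel is a *junction pixel* iff its branch count — the number of
black→white transitions in the cyclic neighbour walk P2…P9,P2 — is ≥ 3.
The textbook junction pattern (four white cardinal neighbours, four black
diagonals) has four transitions and is one case of this criterion; the
transition-count form generalises it to T- and Y-junctions of any
orientation. Junction pixels within **3 px** (single linkage) merge into
one junction at the rounded cluster centroid.

## Corrugation and lofting

Out-of-plane shape is encoded in a secondary grayscale image of the same
size: `z = peak · (1 − v/255)`, so white lies in valleys (z = 0) and black
on hills (z = peak). The image is sampled along `n_sections ≥ 2` equally
spaced vertical section lines (a 3-column band is averaged against noise);
each height profile is smoothed with a 1-D Gaussian of
`σ = 4 / sharpness` px — the smoothing emulates the soft greyish fade next
to height maxima that avoids physically implausible height jumps, and the
Gaussian form plus the 4-px constant are this package's own choice (the
knob has no published transfer function). Between sections, height is
interpolated linearly along the horizontal axis — the linear loft path.
`peak = 0` reduces the shell exactly to the planar model.

The lofted sheet is trimmed to the wing outline on a regular grid: a grid
quad is kept iff its centre falls inside the outline (and outside every
hole), so boundary staircase errors cancel instead of biasing the mesh
small; corner vertices falling outside are snapped to the nearest boundary
point, keeping every vertex inside or on the outline. Each kept quad is
split into two triangles. Planar models use the *same* trimmed-grid mesher
at z = 0, which is why a zero-peak shell exports a vertex-identical mesh to
the planar model. A constrained-Delaunay face triangulation was considered
and rejected: the trimmed grid serves both planar and shell exports with
one code path, and mesh quality is irrelevant here because solver meshing
is delegated to the FE package.

## Model assembly and export

A wing model bundles the outer boundary, cell partitions, hole cuts, a
material section assignment, and (for shells) the lofted surface. Material
grouping is either *two-section* (one section for all veins, one for all
membranes) or *multi-section* (one per cell plus one for veins). Default
material constants are the published hawkmoth-forewing validation values —
membrane modulus 1.5×10⁸ N m⁻², vein modulus 2.1×10¹² N m⁻², tip point
load 0.003 N — recorded in the emitted script and overridable; they are
never baked into geometry. Shell thickness defaults to 1.0 per section
(solver units; no published value exists, set it per study).

The solver script is emitted as deterministic Abaqus-dialect Python text —
outline sketch, hole cuts, one face partition per cell, `n` loft-section
definitions plus one linear loft path for shells, one material/section
definition and exactly one section-assignment statement per section. The
script is validated grammatically (it parses as Python) and structurally;
no solver is executed. Neutral exports are OBJ and ASCII STL (pixel-derived
coordinates) and a JSON topology dump that round-trips losslessly.

## Synthetic study conditions

The fixture generator emulates the features the pipeline consumes: a closed
silhouette (ellipse, axis ratio ≈ 0.55), convex cells tiling the interior
(bounded Voronoi tessellation of Mitchell best-candidate points), constant
stroke width (default **3 px**), optional holes with torn rims, and an
analytic secondary height image. Rendering is binary — a pixel is black
iff its centre lies within half a stroke width of a vein centreline — so
pixel-level oracles are exact. Validity constraints make ground truth
usable: analytic cell area ≥ **250 px²** (cells must survive the stroke)
and ground-truth junction separation ≥ **7 px** (two junctions closer than
twice the 3-px match tolerance are not individually resolvable);
candidate tessellations violating them are resampled deterministically
from the same stream. Fixture sizes default to 300×450 px with 5–30 cells,
comparable to wing photographs normalised to a few hundred pixels of span.

Because boundary chains pass through black pixel centres, truth cell
polygons are the Voronoi cells eroded by `(vein_width − 1)/2` rather than
`vein_width/2` — the convention that matches what a boundary-pixel polygon
measures on axis-aligned edges.

What passing these conditions does **not** show: robustness to grayscale
gradients, shading, pigmentation spots, anti-aliased or compressed images,
non-constant vein width, or curved veins between junctions. The quality
screens flag some of these; none are corrected automatically.

## Known limitations

* Boundary chains follow the vein-facing side of the black boundary ring;
  on oblique edges that side sits up to half a pixel inside the stroke
  band, so measured cell areas run ≈2 % high on small cells (worst ≈5 % at
  3-px vein width, shrinking with cell size). Length is far less sensitive
  (≤0.5 % typical).
* Hole/cell discrimination is manual by design (a hole is pixel-wise
  indistinguishable from a cell).
* Vein cross-sections, non-homogeneous thickness fields, and solver
  execution are out of scope; the exported script delegates meshing,
  loading and solution to the FE package.
* Corrugation comes only from the user-drawn secondary image; the package
  does not infer 3-D shape from photographs.
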