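# Methods

## The quantification model

`layerquant` treats the embryo body wall as a continuous sheet of cells
between two closed boundary curves, and gene expression as a scalar
function of position along that sheet.  Three assumptions underpin the
whole pipeline:

1. **Stain is dark on light.**  Expression units are inverted intensity,
   `(255 − value)/255`, so more stain means more expression.  Channel means
   are taken per segment; the greyscale channel is the unweighted mean of
   the three channel means (luma weights can be supplied instead via
   `grey_weights`).
2. **The cell layer carries the signal.**  Intensity is averaged over
   quadrilateral segments spanning the layer, not over the whole embryo, so
   out-of-layer background contributes only through the baseline that the
   editor subtracts.
3. **Transparency for 3D work.**  Reconstruction from views assumes the
   whole expression domain is visible in each view (maximum expression =
   darkest pixel along the ray).  Occlusion of the endoderm in oral views
   is a known limitation of the two-view model and is not corrected.

## Coordinates and conventions

Images are indexed (row, col); a geometry point's `x` is the column and `y`
the row direction, origin top-left, pixels throughout.  Node rings are
normalized on construction to positive shoelace area in (x, y); boundary
markers and the aboral anchor are stored as arc-length fractions so that
node-wise averaging of geometries keeps them meaningful.  In volumes the
primary (oral–aboral) axis is `x`, views share `z`, and `P` is indexed
`[x, y, z]`; this convention is recorded in the JSON sidecar of every
volume file (raw little-endian float32 + sidecar; chosen because it needs
no extra dependency and keeps volumes greppable by any reader).

## Curves and decomposition

Splines use cumulative chord-length parameterization with periodic end
conditions for closed rings (natural for open curves), sampled at 10⁵
points by default — dense enough that nearest-point queries resolve below
0.01 px on a 100 px embryo.  The sampled polyline, not the analytic spline,
is the operational curve: nearest-point matching (KD-tree over the samples,
ties to the lowest index) and arc-length lookup both run on it.

Decomposition parameters:

- `segment_length` (px): target outer-arc length of one segment.  The
  count is `n = round(perimeter / segment_length)` with the residual spread
  evenly, so the closed ribbon is always tiled exactly.
- `gap_factor` (default 1.5): inner-curve arcs between consecutive matches
  longer than `gap_factor × segment_length` are subdivided and matched back
  to the outer curve.  This triggers where the inner wall is locally longer
  than the outer one, i.e. in the concave invagination region.
- `smoothing_span` (default 3, odd): width of the circular moving average
  applied once (configurable passes) to the boundary arc positions on each
  curve.  Uniformly spaced boundaries are a fixed point.

Pixel membership uses the even-odd rule with pixel centers at
(col + 0.5, row + 0.5) and a strict `x < x_intersection` comparison, so
adjacent segments sharing an edge claim boundary pixels consistently;
segments are clipped at image borders with a warning.  A segment that
captures no pixel center gets its means by circular linear interpolation
from its neighbours and is flagged.  Sub-pixel area weighting of boundary
pixels is deliberately not attempted.

## Profile editing and standardization

Editing operations change values only, never positions, and treat the
profile as a closed loop (the ribbon is closed), hence:

- the moving-average window is circular, preserving the circular mean
  exactly;
- symmetrization reflects about the decomposition start (the aboral
  anchor), `v'(s) = (v(s) + v(L − s))/2`, with the mirrored value read off
  by circular linear interpolation — idempotent, and a fixed point for
  mirror-symmetric profiles;
- baseline subtraction clamps at zero, since negative expression is not
  meaningful;
- interval repair requires flanking context (2 points per side for linear,
  4 for cubic spline and PCHIP) and refuses intervals touching the ends.

Standardization maps arc position to the normalized coordinate by a
piecewise-linear map through five landmarks: aboral anchor → −50, first
boundary → −pin, endoderm arc-center (midpoint of the two boundary
positions) → 0, second boundary → +pin, anchor again → +50.  The pin
default is ±25, placing the boundaries halfway between endoderm center and
aboral pole; it is configurable because the boundary fraction varies with
stage.  Blastula profiles (no endoderm) use the three-landmark map oral
pole → 0, aboral → ±50.  The output grid has 101 points so the integer
positions −50…+50 all exist; values are resampled linearly and rescaled to
maximum 100 (`rescale=False` keeps raw units when several profiles must
share a scale).  An all-zero profile raises unless `allow_zero` is set.

## 3D reconstruction, slicing, landscapes

View alignment fits the 1D affine map on z (scale + shift) by least
squares over matched reference points and resamples the oral image
bilinearly; coordinates within 10⁻⁹ of an integer are snapped so an
identity alignment is exact.  Two-view mixing takes the voxel-wise minimum
of the two view expressions — a voxel carries signal only if both views see
signal on its rays — which makes the reconstruction an outer bound of the
true volume and exact on supports that are intersections of their own
back-projections (e.g. boxes).

Radial reconstruction weights the two arc base points linearly in the
azimuthal angle θ ∈ [0, π], `(1 − θ/π)·I(S1) + (θ/π)·I(S2)`; a smooth
choice that reproduces the input exactly on the image plane and degrades
gracefully between.  Base points are sampled bilinearly; arcs leaving the
image give 0.  Slicing samples full planes through the primary axis at
angles k·180°/n trilinearly (outside the volume → 0); slice 0 is the
original central plane, and for a volume mirror-symmetric about the image
plane the second half of the slices repeats the first half in reverse.

Landscape rows are the standardized profiles of the angular slices
measured with one shared decomposition and edit script.  Rows share a
single intensity scale (global maximum → 100) rather than being normalized
per row: per-row normalization would erase exactly the angular amplitude
modulation the landscape exists to display.

## Clustering

Pearson correlation is computed on the 101-point grid *excluding* the +50
endpoint, which duplicates the −50 aboral sample and would otherwise be
double-weighted.  Distances are d = 1 − r; agglomeration is unweighted
average linkage (UPGMA, scipy implementation); the tree is cut at
cophenetic distance 1 − cut_similarity (default cut at similarity 0.6);
groups are renumbered by first appearance along the dendrogram leaf order
so group 1 sits at the top of the heatmap.  Constant profiles are rejected
with their labels listed, since their correlation is undefined.

## The phantom generator

Phantoms stand in for real micrographs, which ship no ground truth.  They
emulate: a two-layer cross-section (concentric rings for the blastula; a
Gaussian dimple of parametric depth at the oral pole for gastrula stages,
whose angular half-width sets the boundary markers); an expression function
g(s) painted along the ribbon by darkening pixels in proportion to g at the
nearest mid-curve arc position; a light background (default 0.95 of white)
with an optional linear lighting gradient; annotation glyphs as filled
rectangles or discs (only their artefact effect matters, so no text is
rendered); and seeded Gaussian noise, quantized to 8 bits so identical
parameters give bit-identical images.  Phantom view pairs project a known
volume by maximum expression along the ray, with reference points at the
volume corners.

What phantoms do *not* emulate — and what passing tests therefore cannot
show about real data: optical blur and chromatic stain spectra, occlusion
and partial transparency, deformation between perpendicular views,
imperfect manual node placement, and biological variability between
embryos.  Tests on phantoms validate the geometry→profile machinery, not
the imaging physics.

Default test conditions: a 100 px outer radius ring with 20 px layer
thickness on a 256² canvas, 100 segments, noise SD 0.01, a Gaussian bump of
width 0.06 of the ribbon; volumes of 41–97 voxels per side.  These sizes
keep every phantom resolvable well above the pixel scale while the full
suite stays lightweight.

## Numerical choices and degenerate inputs

- Nearest-point ties: lowest sample index (deterministic).
- Exactly uniform inputs: smoothing, symmetrize and moving_average are
  fixed points up to 10⁻¹² arithmetic noise.
- Decomposition failure (crossing radial edges or non-monotone boundary
  order after matching/smoothing) raises with the offending index rather
  than producing a twisted ribbon.
- Registration needs ≥2 non-coincident point pairs; reflections are
  excluded from the similarity fit.
- Cluster tie-breaking follows scipy's deterministic agglomeration order.

## Known limitations

Node correspondence across embryos for averaging is assumed to be
established by the user (equal node counts, matching placement); the
package validates counts only.  The two-view model cannot represent
concavities along a viewing ray (min-mixing overestimates such supports),
and the radial model assigns all off-plane variation to the linear angular
blend.  Neither GUI node dragging nor automatic boundary detection is
provided; node placement is programmatic.
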