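# Methods

`floramorph` quantifies the shape of five-lobed, tubular corollas (the
gloxinia / *Sinningia*-type flower: a fused basal tube opening into five
free lobes) from 3D volumetric images, the way such flowers are scanned by
micro-computed tomography.  It covers the whole chain — volume
segmentation, surface extraction, homologous landmark placement,
generalized Procrustes analysis (GPA) with principal component analysis
(PCA), two bespoke traits (flower opening and corolla asymmetry), and 2D
projections for comparison with photograph-based morphometrics — together
with a parametric synthetic-corolla generator that supplies ground truth
for every stage.

## The landmark scheme

Each petal carries five primary landmarks: the two intersections with its
neighbouring lobes (I and II; II coincides with the next petal's I), the
midrib proximal point (III), the lobe/tube boundary on the midrib (IV) and
the midrib distal point (V).  Two of these are not picked but computed:

- **IV** is the surface point of the corolla mesh with the smallest
  Euclidean distance to the midpoint of I and II.  The search is exact
  over every triangle (closest point on the triangle, not the nearest
  vertex), with ties broken to the lowest face index.
- **V** is the point on the lobe contour equidistant from I and II in the
  geodesic sense, i.e. the arc-length midpoint of the annotated contour
  polyline.  "Geodesic" here means arc length along the annotated
  polyline, not a surface geodesic on the mesh.

Secondary landmarks (semilandmarks) are placed at equal arc length along
four curve segments per petal: 3 on each semi-lobe contour (I–V and V–II),
2 on the lobe midrib (IV–V) and 7 on the tube midrib (III–IV).  Curves are
piecewise-linear interpolations of the annotated point lists (about 70
contour and 80 midrib points per petal).  For five petals this yields
95 landmarks — 20 primary and 75 secondary — of which 55 belong to the
lobe compartment and 50 to the tube compartment, with 10 (intersections
and boundary points) shared.  The counts follow the closed form
`primary = 4n`, `secondary = n(2a + b + c)` for `n` petals and a per-petal
scheme `(a, b, c)`.

Assembly details that the scheme leaves open were fixed as follows:
adjacent petals' picks of a shared intersection are averaged when they
agree within a tolerance (default 0.3 mm) and rejected as inconsistent
otherwise; the midrib polyline is split at the points on it nearest to the
computed IV and V, and the off-curve distance of IV to the midrib is
logged as a quality metric; canonical ordering is petal 0 (dorsal) through
4, and within a petal I, III, IV, V, then the semilandmark blocks.  Flowers
without exactly the expected number of petal annotations are rejected —
only the five-lobed morph is analysed.

## Segmentation

Raw stacks are processed one slice at a time, in stack order:

1. **Base removal** — connected components whose pixel count exceeds a
   threshold (default 300 px) *and* whose centroid lies in a configured
   slice region (default: bottom 20% of rows) are zeroed.  Size alone is
   not sufficient because the flower can out-size the base in some slices.
2. **Contrast stretch** — the 1st/99th percentile intensities are mapped
   to the dtype range, followed by a gamma map (default 1.0); the combined
   transform is monotone.  Constant slices pass through with a warning.
3. **Binarisation** — Otsu's threshold by default (a fixed threshold is
   available); foreground is strictly above the threshold.
4. **Small-object removal** — 8-connected components smaller than
   `min_px` (default 50 px at the 70–100 µm working resolutions) are
   treated as sparkle noise and removed.
5. **Mask and close** — the original grayscale slice is masked by the
   cleaned binary mask, then a grayscale morphological closing with a
   radius-1 disc fills hollow pixels inside the petals.

The cleaned volume is converted to a triangle mesh by marching cubes at an
isolevel of 0.5 on the normalised occupancy, with vertices scaled to mm
(axis convention: array axes (slice, row, col) = (Z, Y, X), world
coordinate = index × voxel size + grid origin).  Optional decimation uses
deterministic vertex clustering with an iteratively coarsened grid; the
face target default is 200k.  Downsampling (block mean over integer
factors, e.g. 35 µm → 70 µm at factor 2) is available for large scans.

## Shape statistics

GPA centres every configuration, scales it to unit centroid size, and
iteratively rotates it onto the evolving mean shape (recomputed and
renormalised each round) until the summed squared distance to the mean
decreases by less than a relative tolerance of 1e-10 or 100 iterations
pass.  Rotations are proper (determinant +1): once dorsoventral labels are
fixed, flowers are chiral and reflections would be anatomical nonsense.
The objective is logged per iteration and is non-increasing.

PCA decomposes the covariance of the flattened aligned coordinates (no
tangent-space projection — the decomposition acts directly on fitted
coordinates; covariance, not correlation, as is standard for Procrustes
coordinates whose axes share units).  Component signs are fixed by making
each component's largest-magnitude loading positive.  Shapes are
reconstructed from manipulated scores by inverse PCA (mean + Σ score ×
eigenvector, unspecified components at their mean), and per-landmark
deformation vectors are the difference between such a reconstruction and
the mean shape.  The code is dimension-agnostic: 2D projected landmark
sets run through the identical path.

## Traits

- **Flower opening** = diameter of the lobe-widening circle (best-fit
  circle through the five V landmarks) divided by the diameter of the
  tube-opening circle (best-fit circle through the five intersections).
- **Corolla asymmetry** = sin θ, where θ is the angle between the corolla
  tube's long axis — the first principal axis of the 50 tube landmarks —
  and the normal of the tube-opening circle, folded to [0°, 90°] to remove
  axis-direction ambiguity.

Circle fitting uses a total-least-squares plane (SVD), in-plane projection
and the algebraic (Kåsa) least-squares circle — deterministic,
iteration-free, and exact whenever the points are exactly co-circular;
an optional geometric refinement minimises true point-to-circle distances
instead (the two agree within 1% radius at realistic noise; the algebraic
fit is the default precisely because five points overdetermine the
circle but never by much).  The opening-circle normal is oriented away
from the tube-proximal centroid (mean of the III landmarks), and the tube
axis from that centroid toward the opening centre, making the angle
well-defined.  Both traits are invariant under translation, rotation and
uniform scaling by construction, which the tests assert at 1e-9.

## 2D views

The front view looks along the tube-opening circle normal with the dorsal
direction (dorsal-petal centroid minus circle centre, projected into the
view plane) as "up"; the side view looks along the dorsoventral-plane
normal.  Projection is orthographic — a perspective camera would introduce
an arbitrary focal length without changing the qualitative comparison.
Front-view 2D landmarks resample each petal's projected lobe-contour chain
at equal arc length into 6 points (the final point of each chain opens the
next petal's, so 5 × 6 = 30 distinct landmarks); side-view landmarks take
the projected dorsal tube midrib (8 points) plus the pointwise mean of the
two ventral-most petals' midribs (7 points), 15 in total.  This
deterministic resampling replaces the manual on-screen picking used in
photograph protocols; it is a simplified, reproducible stand-in, not a
re-implementation of any particular manual protocol.

## The synthetic corolla generator

The generator is the package's ground-truth instrument, and its geometry
is designed so that the *operational* landmark definitions recover the
*generative* parameters exactly:

- The tube is a vessel of horizontal circular cross sections whose centres
  run along an axis tilted by an angle τ in the dorsoventral plane.  The
  radius profile `ρ(t) = ρ_base + (ρ_open − ρ_base) · t(1 + A(1 − t))`
  rises from a narrow base, inflates into a chamber wider than the opening
  (bulge parameter A, default 4.5) and narrows to a constricted rim.  The
  constriction matters: the rim is a steep local radius minimum, so the
  mesh point nearest an intersection-chord midpoint — landmark IV's
  operational definition — is the rim point itself and not a point partway
  down the leaning tube wall.  The generator validates that the rim slope
  exceeds the axial lean.
- The five intersections lie exactly on the opening circle (radius
  `tube_radius`, normal +z), and the five midrib distal points exactly on
  the lobe-widening circle of radius `opening_ratio × tube_radius`, so the
  measured opening equals `opening_ratio` to machine precision.
- The measured asymmetry angle is the angle between the principal axis of
  the 50 tube landmarks and +z.  That axis deviates slightly from the
  construction axis (the horizontal cross-section spread pulls it), so τ
  is found by a bracketed 1-D root solve on the exact analytic
  configuration such that the measured angle equals `tilt_angle_deg` to
  machine precision.  At zero tilt the construction is symmetric and the
  solve is skipped.
- Lobe contours are symmetric bulge curves through the intersections and
  the distal point; because the annotation samples them symmetrically, the
  arc-length midpoint is the distal point exactly.

Voxel export rasterises the mesh surface by dense barycentric sampling,
fills enclosed cavities, and — emulating scan artefacts — adds a bright
half-disc fastening base across the bottom rows of every slice (radius
`base_height`) and isolated bright sparkle voxels at a configurable
background density (default 2×10⁻⁴), all reproducible under the seed.  For
watertight meshes, shell voxels whose centres lie clearly outside the
surface are trimmed, so voxel counts of solid bodies track analytic
volumes (the sphere oracle holds within 5%); open sheets — the corolla
wall is one — keep their full one-to-two-voxel shell, which is also how a
thin petal appears in a real scan.

Default dimensions (tube length 20 mm, opening radius 6 mm, lobe length
8 mm) give a corolla roughly 30 mm across, a small but realistic gloxinia.
Populations draw `opening_ratio` and `tilt_angle_deg` independently from
truncated normal distributions; the defaults (opening 1.74 ± 0.12, tilt
16.19° ± 4.2°) reproduce at the population level the trait means and
spreads the traits are designed around, with the tilt SD chosen so the
*sine* spread is ≈ 0.07 at the mean.  Truncation bounds (opening in
[1.05, 2.2] and below what the lobe length can span; tilt in [0°, 89°))
are logged.

### What the generator does and does not emulate

It emulates the geometry that drives every algorithm in the package —
compartmentalised petal anatomy, an opening × asymmetry morphospace,
scan-like artefacts (base, sparkles, finite voxel size) — and its
annotations play the role of an operator's manual picks, with zero pick
error.  It does **not** emulate petal texture or venation, sepals or inner
organs, non-circular tube cross sections, petal-to-petal asymmetries
beyond the global tilt, annotation noise, or scanner physics
(beam hardening, reconstruction artefacts).  Passing tests therefore
demonstrate correctness of the algorithms under ideal-annotation
conditions, not robustness to operator variability on real scans.

## Numerical choices

- GPA: relative tolerance 1e-10, max 100 iterations; rank-deficient
  cross-covariances raise rather than silently reflecting.
- PCA sign rule: largest-|loading| entry positive; SVD-based, so
  eigenvalues are exactly non-negative.
- Circle fits: algebraic by default; degenerate (collinear) point sets
  raise.  Normal orientation by caller convention as described above.
- Polyline queries clamp to [0, L]; consecutive duplicate points are
  dropped at construction; sub-polylines interpolate their endpoints.
- Landmark IV: exact all-faces search with a triangle-inequality
  prefilter (a face whose nearest vertex is farther than the best vertex
  distance plus the longest edge cannot win); the synthetic meshes carry a
  deliberate asymmetric tessellation phase so the argmin is strict even on
  perfectly symmetric flowers.
- Constant slices: contrast stretch and Otsu binarisation degrade
  gracefully (pass-through / empty mask, with a warning).
- Determinism: every stochastic step (population draws, sparkle
  placement) flows through a seeded `numpy` generator; CLI runs record the
  seed and a config hash in a provenance JSON.

## Problem sizes

The test suite exercises single flowers at 150–300 µm voxels and the
population-scale checks at the working resolution of 100 µm with 57
flowers (a few seconds per flower: rasterisation, 250–300 slices of
segmentation, marching cubes on ~20M voxels, landmarking, traits).
Parameter-recovery checks use populations of 57–200 flowers from
ground-truth landmarks, which are cheap to generate.  These sizes were
chosen to keep a full run on a single CPU in the minutes range while
staying at the resolutions the segmentation defaults are tuned for.

## Known limitations

- The trait recovery through the voxel pipeline inherits a ~1-voxel
  uncertainty in the mesh-derived boundary landmark; at 100 µm this is a
  fraction of a percent on the asymmetry sine for the default flower, but
  grows for very small or very weakly tilted flowers.
- The side-view landmark rule is a deterministic stand-in for manual
  2D picking; absolute 2D variance fractions are therefore not comparable
  to photograph-based studies, only qualitative contrasts (which modes 2D
  views can and cannot see).
- The per-PC match between shape components and generative parameters
  depends on the sampling correlation of the finite population draw: with
  57 flowers, an unlucky draw can rotate the top-2 PCA basis by enough to
  dilute per-PC correlations even though the top-2 subspace recovers the
  parameters almost perfectly (R² ≈ 0.999).
- No sliding of semilandmarks (bending-energy or otherwise): semilandmark
  positions are fixed by arc length, by design.
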