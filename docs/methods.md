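# Methods

`foldscape` measures the shape of folded cortical surfaces and of labeled
brain volumes.  This note documents the models and algorithms, the
parameters that matter, the numerical choices, what the synthetic substrates
do and do not emulate, and known limitations.

## Data model

Surfaces are triangle meshes in world millimetres (the subject's own space),
read and written as legacy ASCII VTK PolyData only — a deliberately narrow
dialect so round-trips are bitwise lossless and test fixtures are
hand-checkable.  Volumes are 3-D NIfTI-1 images with their affine preserved.
Per-vertex measures are real scalar fields; feature and region identities
are integer label fields with background −1.  Per-region results are CSV
tables with deterministic row order.

## Per-vertex measures

**Voronoi area.**  Each vertex receives the area of its mixed Voronoi cell:
non-obtuse triangles are split by the cotangent rule, obtuse triangles give
half their area to the obtuse corner and a quarter to each other corner.
This estimator conserves total surface area exactly, which every area
computation in the package relies on.

**Mean curvature** (default `normal_directions` method).  For vertex v with
outward unit normal n and geodesic-disk members u (disk radius 2 mm by
default, graph-geodesic distances with Euclidean edge weights):

    H(v) = mean over u of  2 · n·(u − v) / |u − v|²

Each term is the normal curvature along the chord to u; on a sphere of
radius R every term equals 1/R exactly, so the estimator needs no empirical
calibration constant.  Averaging normal curvatures over directions yields
the mean curvature.  Sign convention: positive where the surface bends
toward the outward normal (concave fold interiors), negative on convex
crowns — so a sphere with outward normals has H = −1/R.  Two cheaper
alternatives (`area_ratio`, from the area change under one smoothing step,
and `laplacian_filter`, from the normal component of an umbrella-Laplacian
displacement) are provided behind the method switch; they are approximate
and saturate at sharp bends.

**Gaussian curvature** is the angle defect divided by the mixed Voronoi
area.  The discrete Gauss-Bonnet identity (defect sum = 2πχ) then holds to
machine precision on closed meshes, which is the test anchor.

**Wrapper surface.**  Depth needs a zero-depth reference that hugs gyral
crowns but bridges fold mouths; a convex hull fails on globally concave
brains.  The wrapper is the morphological closing of the voxelized mesh
interior with a Euclidean ball probe (radius 5 mm by default; the probe
must be at least the voxel spacing, 1 mm by default).  The closing is
implemented with distance-field level sets rather than binary
dilation/erosion: the exact point-to-mesh distance field is contoured by
marching cubes at the probe radius (the dilation), then the distance field
of that offset surface is contoured again at the probe radius (the
erosion).  Because both fields are smooth where they are contoured, the
wrapper is sub-voxel accurate — on a convex icosphere it sits within
~0.1 mm of the surface at 1 mm voxels, where a binary closing leaves
~0.5 mm of staircase error.  Interior voxelization uses z-column crossing
parity with a deterministic sub-voxel shear to avoid edge-degenerate rays.

**Geodesic depth** is the multi-source Dijkstra distance, along mesh edges,
from the wrapper-contact set — the vertices within 0.1 mm of the wrapper
(`contact_tolerance`).  Contact vertices are assigned exactly zero.

**Travel depth** augments the same graph with straight exterior hops: a
terminal hop from each vertex to its nearest wrapper point when the segment
is unobstructed, and vertex-to-vertex "shortcut" edges between mutually
visible vertex pairs.  Obstruction is tested in two stages: sampled points
along the open segment must not lie clearly inside the voxelized solid
(more than 0.87 voxel from the surface — this catches chords that enter and
leave the solid exactly at their endpoints, which a face-intersection test
excuses), and a vectorized segment-triangle (Möller–Trumbore) test must
find no crossing away from the endpoints.  Candidate shortcut pairs are
pruned to those within 30 mm whose straight distance beats the on-surface
distance and that could undercut the provisional depth (geodesic or
terminal) at one endpoint; this keeps the augmented graph small without
affecting the guarantee that travel depth ≤ geodesic depth, which holds by
construction because the augmented graph contains every mesh edge.  The
nearest-wrapper-point restriction on terminal hops is an approximation:
slanted hops to non-nearest wrapper points are reachable only through
shortcut chains.

Depths are grid-quantities only through the wrapper: rigid motions change
results at the sub-voxel scale of the wrapper reconstruction (curvatures,
which never touch a grid, are rigid-motion invariant to float precision).

## Feature extraction

**Depth threshold.**  Travel-depth histograms of folded surfaces fall
steeply from a low-depth mode (crowns) into a long deep tail (folds).  The
threshold is found on a 100-bin histogram smoothed with a 5-bin moving
average: the first bin past the mode where the centered-difference slope
becomes non-negative.  At least 1000 finite values are required.

**Folds** are connected components of {travel depth ≥ threshold}; folds of
50 vertices or fewer (`min_fold_size`) are discarded; survivors are
numbered 0..K−1 largest first, ties to the smallest vertex index.

**Fundus likelihood** inside a fold is the product of min–max normalized
travel depth and min–max normalized positive mean curvature — deep *and*
curved wins.

**Anchors** are fold vertices whose likelihood is at least two (unscaled)
median absolute deviations above the median of the nonzero values; among
anchors within 10 edges of each other only the higher value survives
(greedy from the highest, index breaks ties).  When the MAD is zero the
cutoff degenerates to the median and the rule reduces to a maximal
10-edge packing — a documented corner.

**Endpoints.**  Seeds are fold vertices within one histogram bin of the
median fold depth.  Concentric rings are hop distances from the fold's
edge; each seed walks edge-ward, always stepping to the highest-likelihood
neighbor strictly closer to the edge, and records its arrival vertex and
the median likelihood along its track.  Candidates on tracks with median ≥
the median of all track medians survive and are then thinned by the same
10-edge rule, which suppresses spurious branching at the fold edge.

**Skeletonization** (`connect_points_erosion`) erodes the fold by
repeatedly removing, in ascending likelihood order (index breaks ties),
vertices that are either *simple points* or curve endpoints, never touching
anchors or endpoints.  A vertex is a simple point when its object-neighbors
form exactly one connected arc of its link that is not the entire closed
link ring (removing the center of a filled patch would open a hole); a
vertex with a single object neighbor is classified non-simple and is
removable only under the endpoint rule.  The result is a 1-vertex-thick
skeleton through the protected vertices that provably preserves component
count and Euler characteristic (tested exhaustively on small patches).

**Sulci.**  A sulcus is the part of a fold whose opposing banks carry a
protocol gyral label pair.  For each pair with both labels present in the
fold, the pair's label boundary seeds a hop-distance propagation that
expands only through fold vertices carrying one of the pair's labels;
a vertex joins the sulcus of the nearest reachable boundary (ties to the
smaller sulcus id).  This single mechanism realizes both protocol cases:
vertices whose label belongs to one pair join it iff connected to its
boundary, vertices whose label is shared by several pairs are split by
proximity.  Fold parts matching no pair stay −1.  `segment_by_region`
intersects fundi with sulci pointwise to produce sulcal fundi.

The packaged protocol table (`data/dkt_sulcus_protocol.csv`) defines 25
sulci per hemisphere from label pairs over the 31 DKT cortical regions per
hemisphere (FreeSurfer-style 1xxx/2xxx codes, 62 labels in total); it was
reconstructed from the protocol's published description, so individual pair
memberships may differ in detail from other distributions of the protocol.

## Whole-shape descriptors

**Laplace-Beltrami spectra** use linear (P1) finite elements: cotangent
stiffness and consistent (non-lumped) mass matrices, natural boundary
conditions on open patches, shift-invert Lanczos for the smallest
generalized eigenvalues.  Closed and Neumann patches carry a ~0 leading
eigenvalue, detected at relative tolerance 1e-8 and dropped before use.
The optional normalization maps λᵢ → λᵢ·A/i over the nonzero eigenvalues
(area A, index i from 1): multiplying by area makes the spectrum
scale-invariant (λ scales as 1/s², A as s²) and dividing by the index
flattens Weyl's linear growth; the normalized sequence need not be
monotone.  Distances between spectra: the plain L2 distance of the first N
nonzero eigenvalues, and the weighted spectral distance (WESD) implemented
as the Lᵖ norm of the difference of reciprocal-eigenvalue vectors
(termwise |λₙᴬ − λₙᴮ| / λₙᴬλₙᴮ, p = 2 by default).  This form is an exact
pseudo-metric (it is an Lᵖ distance), and because 1/λₙ decays like 1/n on
surfaces, truncation increments shrink as N grows.

**3-D Zernike moments.**  The solid bounded by a patch (for open patches,
the cone solid of signed tetrahedra over the origin) is translated to its
volumetric centroid and scaled into the unit ball by its largest vertex
radius.  Geometric moments ∫ xᵃyᵇzᶜ dV up to the requested order are exact:
per face, the tetrahedron integral factorizes into a 3-D convolution of
per-vertex monomial tensors with trinomial weights (no quadrature), batched
with FFT convolutions.  The Zernike basis Zₙₗₘ = Rₙₗ(r)Yₗₘ is built
symbolically as monomial coefficient tensors: solid harmonics from the
standard two-term recurrences (validated against scipy's spherical
harmonics), radial polynomials by exact rational Gram–Schmidt on
{r^l, r^{l+2}, …} under ∫₀¹ f g r² dr.  The descriptor for (n, l) is the
norm over m of the projections Ωₙₗₘ = (3/4π)⟨solid, Zₙₗₘ⟩ — rotation
invariant because the Yₗₘ span a unitary representation; reflection
invariance follows from the norm over m.  Descriptor count at order N is
Σₙ (⌊n/2⌋ + 1): 121 at order 20, 342 at order 35.  Values above 1 trigger
an instability warning.  FFT-based moment assembly is accurate to ~1e-10
at the orders used here (≤ 20); trinomial growth makes orders beyond ~25
progressively less reliable, which the instability warning surfaces.

## Volumetric measures

**Hybrid segmentation.**  Two gray/white segmentations with complementary
error modes are merged voxelwise: non-cortex is the union of both sources'
non-cortex, cortex is the union of both cortex masks minus that non-cortex
(conflicts resolve to non-cortex, preserving white matter inside gyral
folds).  A cerebellum mask overwrites any class afterwards.  Label images
are propagated through the resulting masks by 26-connected in-mask BFS from
all labeled voxels (nearest labeled voxel wins, ties to the smaller label),
which is idempotent and label-conserving.

**Region volume** is voxel count × voxel volume.

**thickinthehead.**  Region thickness = cortex volume of the region /
middle-surface area of the region, after nearest-neighbour resampling by an
integer factor (default 2: 1 mm → 0.5 mm) to better represent cortical
contours.  The default middle surface is the zero level set of
d(background) − d(non-cortex) (exact Euclidean distance transforms), its
area measured by marching cubes with faces clipped to cortex voxels and
assigned to regions by their centroid voxel.  The digitization offsets of
the two distance fields cancel on this level set, so a 3 mm spherical shell
at 1 mm voxels is recovered to ~0.5% and a flat slab to ~4%.  The simpler
estimator that averages the one-voxel inner/outer boundary-layer volumes
divided by the voxel side is available as
`area_method="boundary_counts"`; on the same shell it is biased ~20% high
in thickness because a digital boundary layer under-counts oblique surface
area, and it is retained for comparison rather than as the default.

## Statistics

Eight summary statistics per label or feature: median, unscaled MAD, mean,
population standard deviation, population skewness, excess kurtosis, and
linearly interpolated quartiles.  The MAD is unscaled (no 1.4826 factor)
because the same quantity serves as the raw threshold unit in fundus
anchoring.  `fractional_difference` is |a − b|/a per (region, measure) with
NaN at zero baselines.  `distance_correlation` uses the double-centered
V-statistic form (O(n²)), exactly 1 under affine dependence.
`curve_to_curve_distance` reports mean and max nearest-point Euclidean
distances in both directions, asymmetric by construction.

## Synthetic substrates

The fixture generators provide every geometry the algorithms see in tests:
icospheres (convex reference; analytic area, curvature, spectra), gyrified
sheets with Gaussian-profile grooves (C¹ valleys with unique floor lines —
no plateau ties in anchoring; optionally windowed in y into elongated
elliptical pits), a narrow straight-walled V-groove with a refined x grid
(travel ≈ geodesic regime), a flask-shaped overhung cavity built by
revolution (travel ≪ geodesic regime), spherical-shell segmentations, and
noisy segmentation pairs with source-specific error modes (one loses
peripheral cortex, the other adds exterior gray and loses deep white).
Everything is deterministic given parameters and seed.

These substrates emulate geometry, not imaging: there is no scanner noise,
no partial-volume effect, no topological defects from surface
reconstruction, and desk-scale meshes (10³–10⁴ vertices) rather than
~10⁵-vertex hemispheres.  Passing tests therefore validate the algorithms'
geometric behavior and determinism, not robustness to real-data artifacts.
Problem sizes in the test suite (icosphere subdivision 3–4, sheets of
roughly 40×30 grid points, 20³ label volumes, spectral truncation ≤ 30,
Zernike order ≤ 8 against voxel oracles) were chosen so every oracle is
computable exactly and the full suite runs in minutes.

## Known limitations

- Travel depth's terminal hops use only the nearest wrapper point, and
  shortcut pairs are pruned by a provisional-depth criterion that ignores
  multi-shortcut chains; both can overestimate travel depth slightly in
  pathological cavities (never below geodesic consistency bounds).
- The wrapper inherits a voxel grid; depths are reproducible bit-for-bit
  only for identical grids, and rigid motions perturb them at sub-voxel
  scale.
- Endpoint tracking is a heuristic; on perfectly symmetric circular pits
  the surviving endpoint set depends on the tie-break order (deterministic,
  but not geometrically distinguished).
- The FEM spectrum degrades on patches with highly obtuse triangles
  (cotangent weights go negative); no intrinsic Delaunay retriangulation is
  attempted.
- `zernike_moments` on an open patch describes the cone solid over the
  patch, not the patch itself — by design, but worth knowing when comparing
  across differently-closed patches.
- Anchor selection (median + 2 MAD) can return nothing on perfectly
  translation-invariant grooves, where every floor vertex has the same
  likelihood and no vertex stands out; real sulci (and the windowed valley
  fixtures) taper, which restores the spread the rule needs.
- Morphological closing cannot bridge a cavity whose belly exceeds the
  probe diameter: the wrapper then legitimately follows the cavity wall
  from inside and the cavity floor gets near-zero depth.  The flask fixture
  is sized (belly 9.6 mm < probe 10 mm) to stay in the bridgeable regime.
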