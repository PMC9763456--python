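# Methods

## Scope and design

`cocoscan` reproduces a cone-beam Micro-CT measurement chain for coconut
fruit/seed phenotyping at desk scale. Every stage that would normally
depend on hardware or real scans is replaced by a parametric phantom
whose ground truth is known in closed form, so the whole chain —
simulation, calibration, reconstruction, segmentation, meshing, trait
extraction, regression — is testable end to end with no external data.
Deep-learning segmentation is deliberately out of scope; the classical
semi-automatic algorithm is the default behind a pluggable slice-segmenter
interface.

## Coordinate conventions

Volumes are indexed `[z, y, x]` with z the rotation (vertical) axis.
World coordinates are mm, origin at the rotation centre, voxel centres at
`(i − (n−1)/2)·voxel_size`. The source orbits at radius DSC in the z = 0
plane; the flat detector (distance DSD from the source) has u along the
orbit tangent and v along +z. Detector arrays are `[row, col]` with row 0
at the top.

## Phantom generator

A coconut is a nest of ellipsoids, outside-in: epicarp (skin), mesocarp
(husk), shell (endocarp), solid albumen (copra), and the lumen holding
liquid albumen with an optional air cavity above a horizontal level plane
(`cavity_fraction` of the lumen height). Compartment membership is
decided at voxel centres, which keeps the voxel-count truth exact and
deterministic; a 2× supersampling flag provides partial-volume-averaged
attenuation when wanted. Closed forms: ellipsoid volume 4/3·π·abc,
shell volume = outer − inner, cavity volume from the ellipsoid-cap
integral, surface areas by the Knud-Thomsen approximation (flagged
approximate, ≲1.1% error).

Attenuations are generator parameters, not facts about real fruit
(they were chosen once to reproduce qualitative contrast relations):
liquid albumen = water µ (0.02 mm⁻¹ by default), solid albumen 1.05 µw,
shell 1.8 µw, mesocarp 0.4 µw when mature or 0.9 µw when young (a young,
water-laden husk absorbs more), epicarp 1.8 µw. The epicarp value puts
the skin in the same "dense" image class as the shell: it is a thin
structure, and at a weaker contrast its blurred ring drops below the
dense-class threshold on reconstructed slices, which breaks ring
identification. Real epicarp is waxy and dense, so this is also
physically reasonable.

The reference fruit (128 grid, 1 mm voxels) has outer semi-axes
45×45×55 mm, husk ≈ 11 mm, shell 5 mm, copra 6 mm, `cavity_fraction`
0.25. A dehusked-seed spec (shell + albumen only) mirrors the seed
samples. A seeded smooth roughness field can perturb the outer surface;
it is off by default so closed forms stay exact.

## Acquisition model

The forward projector computes exact voxel-intersection line integrals
(Siddon traversal, numba-compiled) from the source to every detector
pixel, then emits raw frames S0 = (SW−SB)·exp(−∫µ) + SB with flat dark
(SB = 100) and open-beam (SW = 1100) references. Calibration inverts this
exactly: p = ln((SW−SB)/(S0−SB)), clamping non-physical pixels to a small
positive floor (an error if >1% of a frame). The round trip is machine
precision on noiseless data, which the tests assert at 1e−6.

Field-of-view and resolution arithmetic: FOV = detector active area ×
DSC/DSD, pixel pitch at the axis = (width/cols)·DSC/DSD, both floored to
the conventionally printed integer (so 260.75 → 260 mm, 86.38 → 86 µm).
Objects wider than the FOV are not refused: the stack is flagged
truncated and reconstructs with the corresponding edge artifacts, which
mirrors real out-of-range samples.

## Reconstruction

Textbook full-scan FDK with the detector resampled conceptually to the
isocentre scale: cosine/distance pre-weighting dsc/√(dsc²+u²+v²),
row-wise ramp filtering using the exact band-limited Ram-Lak spatial
kernel (h[0] = 1/(4du²), odd taps −1/(πndu)², zero-padded to a power of
two; optional Hann apodization), then distance-weighted voxel-driven
backprojection with bilinear detector interpolation and total scaling
Δβ/2 (each ray is measured twice over 360°). A uniform water cylinder
reconstructs to its true µ within 3% at 64³/90 angles, within ~0.5% at
128³/180 angles.

CT normalization is the two-point affine map sending a measured air
region mean to 0 and a water region mean to 200 (region means over
eroded masks to avoid edge bias); 8-bit slices are the CT values clamped
to [0, 255].

Desk-scale defaults are 128³ grids, 180 angles over 360°, and a detector
scaled to cover the grid (the production-scale 3000³/360-angle setting
exists as a config preset only). A circular orbit does not satisfy
Tuy's condition; the residual cone artifact matters below (segmentation
of low-contrast interfaces).

## Segmentation

The middle-height slice is segmented first: Otsu (8-bit histogram,
between-class variance, ties to the lowest threshold) separates the
fruit; components under 25 px are removed; holes are filled. A
three-class multi-Otsu of the tissue histogram (enclosed gas excluded)
yields the dense threshold; the bright mask's innermost and outermost
annular runs along 720 equiangular rays identify the shell and epicarp
rings. Ring radii are refined per ray to sub-pixel accuracy at the
radial gray-gradient peak (parabolic interpolation) — a plain threshold
crossing is biased when a plateau saturates in 8-bit — and smoothed by
sliding-window (15°) linear fits with 3×MAD outlier replacement,
iterated twice so broad spikes cannot contaminate their own replacement
values. Solid and liquid albumen grow from seed points by 4-connected
breadth-first flooding against a running mean with per-class gray
tolerances (defaults 6); the two classes grow competitively and
contested pixels go to the closer local class level. Leftover interior
pixels are assigned to the value-nearest interior class (the unbiased
half-level split for partial-volume pixels), and a 3×3 majority vote
between solid and liquid removes salt-and-pepper noise (their contrast,
~10 CT units, is only ~2× the reconstruction noise).

Template propagation re-runs the same engine on the next slice with the
eroded (3 px disc) class masks as seeds; classes whose area falls below
25 px drop out. Two guards matter in practice: (a) a single bright ring
is the epicarp if the template has one (the shell would show as a second
inner run) and the ring hugs the fruit surface, else the shell; (b)
propagated liquid seeds must read near the water level (CT 200 ± 2×
tolerance) — without this the liquid template regrows as a phantom
region on solid tissue once the lumen ends.

The cavity rule: connected shell-interior regions at gray ≤ air + 20
become cavity (the paper-style a-priori rule), followed by a 3-D
half-level refinement of the gas/liquid meniscus — a slice cutting the
meniscus averages air and liquid, so voxels are re-assigned by
propagating each phase into the other where the CT value falls on its
side of the midpoint.

In the full simulated pipeline the stack is segmented in CT units
(floats): the dense shell (CT 360) clamps at 255 in the 8-bit export,
which would bias its edges by about a pixel. The 8-bit export is still
produced for viewing and for gray8-based workflows.

Evaluation: per-class precision, recall, F1 and IoU with macro averages
over classes present in the truth; IoU ≡ F1/(2−F1) per class.

## Surface models

Boundary points are centres of compartment voxels with a six-connected
neighbour of another label. Normals come from least-squares planes over
k = 12 nearest neighbours (smallest covariance eigenvector, oriented
outward from the centroid; degenerate neighbourhoods retry with doubled
k). Surface reconstruction is defined by a contract — watertight,
enclosed volume within 3% of the voxel count, within 1.5 grid cells of
the cloud — and implemented as an implicit signed-distance field
(oriented-plane distance to the nearest cloud point near the surface,
inside/outside fill beyond) contoured by marching cubes at the zero
crossing. The zero-crossing placement is unbiased; plain occupancy
binning was rejected because it inflates enclosed volume by about half a
grid cell. Volumes use the signed-tetrahedron sum, areas the triangle
sum (open meshes: area allowed with a warning, volume refused). Masks
already on the CT grid are meshed directly; a smoothing sigma of 1 voxel
is applied only when measuring *areas*, since unsmoothed marching cubes
keeps volume nearly exact but overstates area ~8% through staircasing.

## Traits

21 agronomic entries (lengths, widths, perimeters, shape categories,
thicknesses, weights) and 47 digital entries (volumes, surface areas,
sphere/box descriptors, maximal-section families, CT integrals,
thicknesses; the duplicated "CCTIV" abbreviation is disambiguated as
CoatCTIV/CopraCTIV with originals preserved in metadata). Notable
conventions, all documented because the choice was open:

- Bounding boxes are axis-aligned in the rotation-axis frame; "length"
  is the vertical (z) extent. Extents count voxel cubes, so a digital
  sphere of radius r has box edge 2r+1 cells.
- The minimal enclosing sphere uses a pivoting Welzl-type algorithm:
  support set ≤ 4, exact small-case solver with the circumcentre
  constrained to the support's affine hull (a minimum-norm solution off
  the hull would silently inflate the radius), pivot on the farthest
  outside point; the radius strictly grows, so it terminates at the
  global optimum. For digital traits the sphere encloses the boundary
  voxel *cubes* so Vol ≤ CSVol always holds.
- The maximal inscribed sphere radius is (max EDT − 0.5) voxels — half a
  voxel keeps the ball inside the voxel cubes; a one-voxel mask gives
  half a voxel.
- Cross sections are axial slices; longitudinal sections sample planes
  containing the z axis at 1° steps (configurable), integrating partial
  cells by linear interpolation.
- Perimeters are sub-pixel boundary contour lengths (marching-squares
  polylines), a more accurate estimate of the same digital-boundary
  quantity as weighted chain codes.
- Shape categories: length/width ≥ 1.25 → oblong, ≥ 1.05 → oval, else
  round (thresholds configurable; they are a package convention).
- Weights: liquids convert volume × density directly (water 1.00 g/mL);
  other compartments use configurable densities or a fitted regression
  model; the solid-albumen dry-biomass traits are reported missing
  unless a drying model (dry-matter fraction) is configured.

Trait recovery on the reference phantom (true labels, 1 mm voxels):
geometric digital traits agree with closed forms within 5%, with two
documented quantization effects — box extents quantize by one cell per
axis, and the inscribed-sphere convention subtracts half a voxel; the
worst case for the latter is an even-sized grid whose centre falls
between voxels.

## Regression models

Six single-predictor families. Power/exponential are linearized through
logs (requiring positive data, rejected otherwise with offending rows
named); logarithmic and quadratic are linear least squares; the logistic
y = L/(1+e^(−k(x−x₀))) uses bounded nonlinear least squares initialized
at L = 1.05·max(y), x₀ = median(x), k from the span. Model selection is
by adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) with p the number of non-
intercept parameters; ties prefer fewer parameters, then the canonical
family order. The synthetic recovery benchmark uses per-point 1%
proportional noise at n = 200; the quadratic benchmark samples a
symmetric domain so its three coefficients are near-orthogonal and
individually identifiable at that noise level. Real-data coefficients
(actual copra-weight models) are out of scope by design — they require
destructive reference measurements.

## Pipeline, reproducibility, problem sizes

`run_pipeline` executes phantom → projection → calibration → FDK →
CT normalization → segmentation → meshes → traits, writing every
intermediate plus a manifest with per-stage SHA-256 checksums; a fixed
seed reproduces the run bit for bit. The air anchor comes from an eroded
annulus outside the fruit; the water anchor from the eroded liquid
region (in simulation the true liquid mask is available; on real data a
water calibration fixture serves the same role). The pipeline
reconstructs with the Hann window by default — with a ~10 CT-unit
albumen contrast, ramp-filter ripple otherwise dominates the class gap.

Reference problem sizes (chosen as the package's desk-scale defaults):
128³ grid, 1 mm voxels, 180 angles, 256² detector — the full pipeline
completes in under two minutes on one CPU, and the acceptance benchmark
(water cylinder at 128³) in about one minute. Tests use 64³–96³ for
module-level checks.

## What the phantom does and does not show

The generator emulates geometry, attenuation contrast, cone-beam physics
and the resulting partial-volume/artifact structure. It does not emulate
photon noise, scatter, beam hardening (polychromatic spectra), detector
lag, fiber texture inside the husk, or irregular (non-ellipsoidal) fruit
— so passing tests demonstrate algorithmic correctness and internal
consistency, not field accuracy on real scans. Real-data headline
accuracies from scanner studies are not reproducible here and are
deliberately not claimed.

## Known limitations

- Solid vs. liquid albumen have ~10 CT units of contrast; FDK cone
  artifacts near the lumen bottom shade the solid plateau by several
  units, and segmentation there relies on the local-level competitive
  split. Individual albumen volumes land within ~5% at the reference
  resolution; their union is much tighter (≈0.1%).
- The closed-form cavity volume and the voxel-count truth differ by up
  to half a voxel slab when the liquid level plane aligns exactly with a
  voxel-centre plane (the reference fruit at 128³ is such a case:
  −5.9%). Volume checks therefore compare against the digital
  (voxel-count) reference; the discretization itself converges to the
  closed form as voxels shrink, which is tested separately.
- A circular orbit is Tuy-incomplete; helical trajectories and
  dual-energy contrast are out of scope.
- The classical segmenter assumes ring-like (star-convex) compartment
  geometry about the slice centroid; strongly lobed fruit would need the
  pluggable segmenter interface.
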