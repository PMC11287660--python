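# Methods

This note documents the models, numerical choices and limitations behind
`planktomesh`: mesh morphometry for phytoplankton 3D models, render-vs-SEM
image validation, and equivalent-sphere Mie scattering.

## Mesh model and units

A `TriangleMesh` is an indexed vertex/face array with counter-clockwise
winding encoding the outward normal. STL and OBJ carry no unit metadata; the
toolkit treats coordinates as micrometres, because every morphometric
quantity of interest (μm, μm², μm³) is on the cell scale, and exposes a
scale factor (`--units-scale` / `TriangleMesh.scaled`) for files in other
units. On STL load, duplicated corner vertices are merged by *exact* float
equality. A tolerance weld would be lossy and non-deterministic in corner
cases; exact merging is reversible and makes topology checks well defined.
Degenerate faces (repeated vertex index) are dropped by default or rejected
on request; they carry no area or volume.

## Morphometry

* **Surface area**: Σ ½‖(v₁−v₀)×(v₂−v₀)‖ over faces. Exact for the mesh,
  invariant to rigid motion and vertex ordering.
* **Biovolume**: divergence-theorem sum |Σ v₀·(v₁×v₂)|/6. The absolute
  value is taken at the end so that a globally inverted mesh (both winding
  conventions occur in STL files in the wild) still gives a positive volume.
  This is the *total* enclosed volume — wall/frustule thickness is not
  subtracted, so it is an upper bound on cytoplasmic volume.
  Preconditions, enforced before summing: every undirected edge shared by
  exactly two faces (watertight) and traversed once in each direction
  (consistently oriented). A mixed-winding mesh can be repaired with
  `fix_orientation`, a breadth-first propagation over the face-adjacency
  graph; the repair fixes relative orientation per shell only, which is
  sufficient because of the absolute value above.
* **Equivalent diameters**: d_ESA = √(SA/π), d_ESV = (6V/π)^(1/3). The
  isoperimetric inequality guarantees d_ESA ≥ d_ESV, with equality only for
  a sphere, so the ratio is a convenient sphericity index; the property is
  asserted for every watertight fixture in the test suite.
* **Extents**: the principal axes are eigenvectors of the exact
  area-weighted covariance of the surface, Σ_T ∫_T (x−x̄)(x−x̄)ᵀ dA with the
  per-triangle closed form (A/12)(Σᵢ cᵢcᵢᵀ + s sᵀ), s = Σᵢ cᵢ, cᵢ the
  centroid-shifted corners. A per-vertex weighting (one third of incident
  face area) was considered and rejected: it depends on how quads happen to
  be split into triangles and skews the axes of a plain box, whereas the
  surface integral is triangulation-independent and reproduces box extents
  exactly. Extents are max−min vertex projections on the axes, sorted
  descending (length ≥ width ≥ depth); ties are broken by lexicographic
  order of the sign-normalised axis vectors so output is deterministic.
  Because published model measurements do not always state whether extents
  were taken along principal axes or the as-exported frame, both are
  exposed (`principal_extents`, `axis_aligned_extents`); principal is the
  default.

Numbers are kept at full precision in the library; the CLI's `--round2`
flag provides the two-decimal presentation customary in morphometry tables.

## Geometric shape proxies

Spheres, spheroids, ellipsoids, capsules and cylinders use the classical
closed forms. The general ellipsoid surface area uses the Thomsen
approximation with p = 1.6075 (documented worst-case error ≈ 1.1%; tests
bound it against the exact spheroid formulas). The pyriform drop is
parameterised by length L, maximum width W and a `shoulder` fraction
locating the widest point: a quarter-ellipse anterior profile (rounded tip,
vertical tangent at z = 0) joined C¹ at the shoulder to a parabolic
posterior taper ending in a point at z = L. The exact analytic profile is a
package choice — real pyriform cells are only qualitatively drop-shaped —
and its SA/V are evaluated by adaptive quadrature of the surface-of-
revolution integrals.

## Synthetic fixtures

The generators exist so that every test and the acceptance script run
without any external model download.

* **Icospheres**: subdivided icosahedra projected to the sphere; 20·4^s
  faces, vertices exactly at radius r. As inscribed polyhedra their SA and
  V converge to 4πr² and (4/3)πr³ monotonically from below — the test suite
  uses this as a refinement-convergence oracle. Refinement is capped at 7
  (≈ 328k faces) to keep fixtures desk-scale.
* **Surfaces of revolution** (spheroids, capsules, drops): rings of
  `n_theta` vertices at profile stations, poles closed by triangle fans so
  watertightness holds at any resolution. Curved sections are sampled by
  angle, not uniformly in z, so convergence to the closed forms is fast;
  the defaults (n_theta = n_z = 128) put volume within ~0.05% of analytic.
  Presets: `p-micans-like` (drop, L = 40 μm, W = 25 μm, shoulder 0.5) and
  `halamphora-like` (prolate spheroid, a = b = 1.97 μm, c = 8.135 μm),
  matching the gross dimensions of the two study organisms.
* **Jitter**: optional "biological variability" displaces vertices along
  vertex normals by uniform noise, capped at 1% of the half-diagonal —
  small enough to preserve watertightness and avoid self-intersection —
  under an explicit seed.
* **Image pairs**: a filled ellipse (semi-axes 35%/25% of the frame) with a
  radial brightness ramp (0.9 → 0.35 of full scale) on a dark (3%)
  background; the distorted partner applies a known monotone transform
  (e.g. gamma) plus optional Gaussian noise, clipped and quantised to 8 or
  16 bits. The generator emulates a single bright specimen on a dark SEM
  filter with a rich intensity histogram. It does **not** emulate SEM
  texture, ornamentation, charging artefacts, background impurities or
  pose mismatch — so passing tests demonstrate the pipeline's correctness
  on its stated assumptions (pre-aligned pair, single dominant object,
  monotone photometric distortion), not robustness to messy field imagery.

## Image validation pipeline

Stages, in order, for a pre-aligned render/SEM pair (geometric registration
is deliberately out of scope — views are paired manually, as in practice):

1. **Mask** from the SEM image: Sobel gradient magnitude → Otsu threshold →
   morphological closing (disk radius 3) → hole fill → keep components
   covering ≥ `min_object_fraction` (default 1%) of the frame. A constant
   image or an empty size filter raises a diagnostic error.
2. **Histogram matching** of the render to the SEM image, restricted to
   in-mask pixels (matching over background would bias the mapping).
   Midpoint (average-rank) CDF convention: value v maps to the reference
   quantile at (count_below + ½·count_equal)/n. Consequences, both tested:
   a constant source maps to the reference median, and the operation is
   exactly idempotent. Output pixels are float-valued within the bit-depth
   range — requantising would break exact idempotence for no benefit.
3. **Relative difference** per pixel: |X^M − X^S|/X^S, normalised by the
   SEM pixel (the measurement), hence deliberately asymmetric in its
   arguments. Pixels with X^S = 0 are excluded and counted
   (`excluded_zero_pixels`) rather than epsilon-regularised: exclusion
   avoids an arbitrary constant and is reported transparently. Mean and
   median are computed over defined in-mask pixels; the map carries NaN
   sentinels elsewhere.

## Mie scattering

Homogeneous-sphere Lorenz–Mie series with the standard stable evaluation:
logarithmic derivative D_n(mx) by downward recurrence started 16 orders
above max(N, |mx|); Riccati–Bessel ψ_n(x), χ_n(x) by upward recurrence;
truncation at the Wiscombe order N = ⌈x + 4x^{1/3} + 2⌉ (tests confirm
longer series change Q_sca by < 1e−8 relative). Defaults follow the
optical-oceanography convention for phytoplankton: λ = 0.532 μm and
relative index m = 1.05 + 0.01i, taken as given (no extra medium-index
division; a `--medium-index` flag rescales the wavelength for users who
want in-water wavenumbers).

Outputs: DSCS_HH(θ) = |S₂|²/k² (parallel polarization, the conventional
plotted quantity) and DSCS_VV = |S₁|²/k², on a 0–180° grid (default 181
points); Q_sca, Q_ext and C_sca, C_ext from the coefficient series; and the
backscattering cross section C_bb = ∫_{90°}^{180°} DSCS·2π sinθ dθ by
trapezoid quadrature on the configured grid — grid-dependent but
reproducible. The DSCS used for C_bb and for the full-sphere consistency
check is the unpolarized average (HH+VV)/2, since only that integrates back
to the series C_sca. Quadrature consistency holds to 0.1% once the grid
resolves the forward lobe (≈ 1/x radians): at 1° resolution this means
x ≲ 6; larger spheres need proportionally finer grids, and the tests check
both regimes.

The independent test oracle evaluates a_n, b_n directly from scipy's
complex-argument spherical Bessel functions — no logarithmic derivative,
no downward recurrence — and agrees with the implementation to better than
1e−6 relative on a grid of (x, m) cases.

Not modelled: non-spherical or coated/heterogeneous particles (T-matrix and
layered-sphere methods are external tools; their truncation parameters such
as Nrank/Mrank do not apply to the Mie series here), and radiative
transfer. Equivalent-sphere spectra are baselines, not predictions of a
real cell's scattering.

## Problem sizes

Defaults were chosen so the whole suite runs in seconds on one core while
staying comfortably inside every stated tolerance: icospheres at 4
subdivisions (5120 faces, SA within 0.13% of analytic), revolution meshes
at n_theta ≤ 256, images at 256×256, Mie up to x ≈ 160 (the 27.3 μm
equivalent sphere at 532 nm, a ~120-term series).

## Known limitations

* Biovolume is total enclosed volume; no wall-thickness correction.
* One mesh at a time: no population statistics across individuals.
* Geometric registration of render/SEM pairs is the user's responsibility.
* STL float32 round-trip loses precision beyond ~7 significant digits;
  OBJ output preserves float64 exactly (17 significant digits written).
* The drop profile is one smooth parameterisation of "pyriform"; cells
  with flattened or asymmetric cross sections need a real mesh.
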