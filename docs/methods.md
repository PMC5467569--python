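# Methods

## The problem and the model

A curled 3D specimen (the motivating case is an E10.5 / Theiler-stage-17
mouse embryo) carries its anatomy along curved body axes, so Cartesian
voxel coordinates are anatomically meaningless. The package defines a
**straight reference space** in which the anatomical axes *are*
Cartesian — world z anterior→posterior, world y dorsal→ventral
(ventral positive), world x left→right as seen looking from the dorsal
side — and fits an invertible mapping T between curved and straight
space from user-supplied landmark pairs. Pulling the straight-space
coordinates back through T defines A–P, D–V and L–R (and
medio-lateral, ml = |lr|) at every voxel of the curved model; pushing
planes and expression patterns through T⁻¹ and T supports
cardinal-plane sectioning and axial analysis of expression domains.

### Constrained distances

All kernel distances are **constrained (geodesic) distances**:
shortest-path lengths on the 26-connected graph of in-mask voxels with
Euclidean inter-centre edge weights (anisotropic spacing respected),
computed with Dijkstra's algorithm (`scipy.sparse.csgraph`). Paths
never leave the specimen mask. This is the property that makes extreme
bending tractable: in a half-circle curl the head and tail are close
in space but far through the body, so the deformation model treats
them as independent.

The graph metric overestimates the true geodesic by at most the
26-neighbour chamfer constant |(1, √2−1, √3−√2)| ≈ 1.1281 (worst-case
direction families like (1,1,3)); this inflation is accepted and
bounded by a property test against a brute-force Dijkstra oracle.
Dijkstra ties resolve by scipy's deterministic scan order, making
distance maps, paths and subdivision reproducible bit-for-bit.

### The deformation model

Displacements are interpolated as

u(p) = Σᵢ wᵢ φ(d_c(p, sᵢ)) + A·(1, p),  φ(r) = √(r² + δ²),

with exact interpolation conditions u(sᵢ) = tᵢ − sᵢ and the moment
side-conditions Pᵀw = 0 (P the affine design at the landmarks). The
affine term makes global translations/affine maps exactly reproducible;
the side conditions keep the kernel part orthogonal to it.

Parameters (all in `CdtParams`):

| parameter | default | meaning |
|---|---|---|
| `delta` | 0.1 × mean constrained nearest-neighbour landmark separation | multiquadric shape, world units |
| `include_affine` | on | affine term + side conditions |
| `regularization` | 0 | ridge on the kernel block (0 = exact interpolation) |
| `connectivity` | 26 | voxel graph neighbourhood |
| `inversion_tolerance` | 0.5 × min spacing | target round-trip error, world units |
| `max_newton_iters` | 20 | inverse refinement iterations |

**Why δ is small.** With distances measured in a non-Euclidean
(geodesic) metric, the multiquadric kernel matrix is *not* guaranteed
conditionally positive definite. Sweeping δ on the phantom showed that
values near the nearest-neighbour separation intermittently cross
near-singular configurations whose interpolants oscillate wildly
between landmarks (field errors of tens of voxels with tiny landmark
residuals). At δ ≈ 0.1 × the NN separation the kernel is close to the
piecewise-linear ‖r‖ basis and was uniformly stable; that is the
default. A diagnostic warns when the fitted weights are large relative
to the displacement scale (the signature of an oscillating
interpolant).

**Dense evaluation.** The displacement is evaluated on the full voxel
grid: exactly at in-mask voxels; within a 2.5-voxel boundary band with
distances continued as d(nearest in-mask voxel) + Euclidean remainder
(so trilinear interpolation stays accurate across the mask surface,
and surface landmarks digitised slightly off-mask behave sensibly);
farther voxels copy their nearest computed value. Query points up to 2
voxels off-mask are evaluated in place on this extended field; farther
points are rejected.

**Inversion.** The inverse field is initialized by the role-swapped
RBF fit in straight space and then refined voxel-by-voxel by Newton
iteration on x + u_fwd(x) = y (Jacobian from central differences of
the forward field, damped fixed-point fallback where the local
Jacobian is near-singular, step capped at 4 voxels). The fit then
*measures* the round-trip error ‖T⁻¹(T(p)) − p‖ on ~1000 sampled
in-mask voxels and stores mean/p99/max in the results object; a
warning names the worst voxel when p99 exceeds the tolerance, and the
fit aborts only if more than 10% of samples exceed ten times the
tolerance (catastrophic non-invertibility). A hard error on single
non-converged voxels would make legitimately coarse fits — the
starting point of landmark subdivision — unusable.

### Landmark subdivision

`subdivide_landmarks` inserts, between consecutive same-prefix pairs,
a new pair at the constrained-geodesic midpoint (by arc length) in the
source and target masks respectively — densifying correspondence
without new manual annotation. Midpoints colliding with an existing
landmark (e.g. the dorsal→ventral path passes through the midline
point) are skipped. The midpoint correspondences carry ~1 voxel of
discretisation noise (chamfer error; under strong curl the source
geodesic also cuts the bend's corner slightly), so refinement is
monotone only down to that noise floor: subdividing a coarse set
improves the fit, subdividing an already sub-voxel fit can degrade it
by a fraction of a voxel. The test suite asserts the floor form of the
property (subdivision never pushes the midline-straightening RMS above
max(base RMS, 1 voxel)).

## The phantom

The synthetic test bed is a tube of tapering radius (10 → 6 voxels)
swept along a planar circular arc in the x = 0 plane, bending toward
−y so the dorsal surface faces −y; the matching straight model is the
same tube along the z-axis with identical arc length L (default 72% of
the grid z-extent, ≈ 68 world units on the default 96³ grid at unit
spacing). Four limb buds (capsules along ±x) attach at arc stations
0.55 (forelimbs) and 0.82 (hindlimbs). Because the midline is a
circular arc, arc length, local frames and nearest-point projection
are closed-form, so every voxel's true A–P (arc length), signed D–V
and signed L–R are analytic — the ground truth against which the
fitted transform is scored.

Content emulating the real use case, all deterministic given the
config seed:

- a midline "Shh-like" marker (voxels within 1 voxel of the midline)
  plus a posterior-distal cap in each limb bud (the zone-of-polarizing-
  activity pattern);
- planted spherical expression domains named after the Fgf family:
  an anterior→posterior craniofacial sequence (Fgf8, Fgf9, Fgf20), a
  dorsal midbrain domain and a bilateral hindbrain pair (Fgf10),
  strictly-left/strictly-right hindbrain domains (Fgf17/Fgf18), a
  trunk pair (Fgf5/Fgf6), and proximal/distal forelimb domains
  (Fgf10/Fgf8) — together exercising all five relation vocabularies;
- anatomical regions by arc-length band (craniofacial, midbrain,
  hindbrain, trunk) plus one region per limb bud;
- default curl angle π (a half turn — the hard case), grid 96³,
  25 landmarks.

**Landmark station rule.** Landmarks sample matched arc-length
stations: a midline pair plus dorsal and ventral surface pairs at
every station, one tip pair per limb, and a left/right surface pair
only when there are no limb tips (otherwise every point would lie in
the x = 0 plane and the affine term would be unidentifiable). The
dorsal/ventral pairs are essential, not decorative: in the bending
map, straight-space z depends on the dorso-ventral offset through the
local turning angle (∂z/∂dv = −sin α), and only surface pairs observe
that shear. Stations are spaced Chebyshev-style (clustered toward the
ends, where |sin α| and hence the shear is largest) with a small
seeded jitter; all landmark coordinates are snapped to voxel centres
so the interpolation conditions hold exactly at the stored points.
This placement mirrors practice on real specimens: midline-marker-
guided points first, surface points at the extremes, limb tips at the
ZPA.

**What the phantom does not emulate.** Real embryo surfaces (branchial
arches, heart bulge), intensity inhomogeneity beyond mild radial
shading and seeded noise, non-planar body axes, imaging artefacts, and
manual landmark placement error. Passing the phantom therefore
demonstrates correctness of the geometry and the numerics under a
known large deformation, not robustness to real-image segmentation or
annotation noise.

## Axial profiles and relations

An expression domain is `volume ≥ threshold` (inclusive) inside the
embryo mask. Its axial profile partitions the in-mask coordinate range
into half-open bins (last bin closed) and reports per-bin occupancy.
The default denominator is the embryo-mask voxel count *in the bin*
(expression per unit volume along the axis); a `denominator="domain"`
flag normalises by the domain's own size instead, since "fraction of
volume occupied" admits both readings. Peak extraction breaks ties
toward the smaller coordinate (most anterior).

Paired relations compare median coordinates (median, not centroid:
robust to stray mapped voxels) within a caller-supplied named region
and assert a direction only when the medians separate by more than a
margin (default 2 voxel spacings — separations below that are within
the mapping's own error). For L–R, domains are first classified as
bilateral (≥ 20% of mass on each side of the midline by default); if
either is, both are decomposed into 26-connected components and
component medians are compared, which is how a midline domain comes
out `medial_to`, `left_of` *and* `right_of` a bilateral partner —
reported together rather than suppressed, since the medio-lateral
vocabulary is what disambiguates the pair. Every assertion is emitted
with its dual. Proximo-distal relations activate when a proximo-distal
coordinate field (constrained distance from the limb attachment) is
supplied for an appendage region.

## Numerical choices, sizes and limitations

- **Problem sizes.** The study phantom is a 96³ grid (~18,600 in-mask
  voxels, 25 landmarks); the full test suite runs in about half a
  minute and the acceptance script in well under one, on a single CPU.
- **Degenerate inputs.** Empty masks, empty domains, all-zero
  profiles, constant colourmap fields, planes missing the mask, and
  disconnected landmark pairs all have defined behaviour (error or
  warning as contracted, never silence).
- **Folding under extreme curl.** With 25 landmarks and a half-turn
  curl, the reconstructed forward field contains a small fraction
  (roughly 1–2%) of folded voxels (det J ≤ 0) near the tube caps and
  limb junctions. In fold pockets no pointwise inverse exists, so
  while the *mean* round-trip error stays well under half a voxel,
  the tail (p99) reaches a few voxels there. On a quarter-turn
  phantom the same pipeline is fold-free and over 99% of points
  round-trip within half a voxel (both behaviours are asserted by the
  test suite). Denser landmark sets reduce folding.
- **Plane tilt near limb attachments.** Limb-tip landmarks carry their
  attachment station's midline displacement and locally flatten the
  A–P shear, so transverse planes extracted exactly at a limb
  attachment can tilt beyond 10° from the perpendicular; at the
  quartile A–P levels the tilt stays below ~10° across station-jitter
  seeds.
- **Determinism.** Identical config + seed reproduce phantom bundles
  and serialized transforms byte-for-byte; all stochastic steps
  (station jitter, sampling) draw from `numpy.random.default_rng`
  seeded explicitly.
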