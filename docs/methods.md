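# Methods

## Coordinate conventions

All algorithms operate in world RAS millimeters; the TrackVis (`.trk`)
voxel-mm dialect is converted at the I/O boundary. A `SpatialReference`
holds a 4×4 affine mapping voxel *indices* (center convention) to world mm.
`world_to_grid` adds 0.5 after applying the inverse affine so that voxel
`(i, j, k)` occupies the half-open cube `[i, i+1)³` in grid coordinates:
`floor` is then the point→voxel map, the lower cube face is inclusive and
the upper exclusive, and no point is counted in two voxels. Consecutive
duplicate points are removed at load (they break distance and traversal
math) and polylines with fewer than two points are rejected.

## Linearization

A streamline is compressed by a greedy forward scan with *backward
verification*. From the last kept point `a`, the candidate chord is
extended one input point at a time; extending to `next` requires that every
intermediate point lie within **MET** of the infinite line through `a` and
`next` and that `‖next − a‖ ≤ MLD`. When the collinearity check fails
(an intermediate point adds shape information) or the span check fails
strictly (`> MLD`), the *previous* candidate — the last point whose chord
passed full verification — is kept and the scan restarts from it.

Choices that the problem statement leaves open, fixed here:

* **Which point is kept on a violation.** Keeping the last *passing*
  candidate (not the violating point) makes the MET bound hold by
  construction: the chord to every kept point is one that was verified.
* **Distance to the infinite line, not the clamped chord.** Intermediate
  points project inside the chord in practice; the infinite-line
  cross-product distance is the standard collinearity test and cheaper.
* **Strict Euclidean MLD comparison.** The span constraint is a radial
  distance from the last kept point; strictness makes `MLD` itself
  attainable (a 30 mm line sampled at 0.5 mm with `MLD = 10` keeps points
  exactly 10 mm apart).
* **`met = 0`** removes only exactly-collinear points, with a 1e-12 mm
  tolerance absorbing float noise.
* **Over-long input steps.** Input steps longer than MLD cannot be
  shortened by point removal; the polyline is split at such steps and each
  run linearized independently, so both endpoints of the long step survive
  verbatim. The MLD output bound therefore holds exactly whenever the input
  respects it, and degrades only to the input's own maximum step otherwise.
* **Defaults** `met = 0.2 mm`, `mld = 5 mm`: a configuration appropriate
  for probabilistic-like streamlines at a 0.5 mm step size; `mld = inf`
  gives unconstrained linearization.

Idempotence note: for `met = 0` and for exactly collinear geometry a second
pass is the identity; for general inputs a second pass may remove further
points (the first pass can create longer, still-nearly-collinear chords)
but never adds any — the tests assert the non-increasing form.

## Progressive ROI selection

ROIs are closed, consistently wound triangle meshes (validated at
construction): boxes (12 triangles), ellipsoids (subdivided icosphere
scaled per-axis), or externally supplied PLY/OBJ meshes. Geometry kernels
are vectorized numpy: Möller–Trumbore segment–triangle intersection,
crossing-parity point-in-mesh with fixed fallback ray directions for
edge-grazing rays, and an Ericson-style closest-point-on-triangle distance.
Boundary contact counts as *inside* everywhere (inclusive ε = 1e-9 mm),
which keeps the point and segment predicates consistent on ROI faces.
Exactly coplanar grazing contacts of a segment along a face are resolved by
the endpoint-inside clause and the adjacent non-coplanar triangles.

Phase 1 queries an octree over all tractogram points (payload: streamline
id, point index; leaf capacity 64, max depth 10; points exactly on a split
plane go to the lower child for determinism) with the ROI's AABB and tests
the candidates for mesh inclusion. Phase 2 inflates the AABB per-axis by a
scalar `L`, drops points of already-selected streamlines, and tests the up
to two segments incident to each remaining candidate point for mesh
intersection. With `L` = the dataset's maximum segment length
(`"complete"`), any segment intersecting the mesh has an endpoint within
`L` of the surface and hence inside the inflated box, so the progressive
result provably equals the brute-force all-segments scan; `"heuristic"`
uses the mean segment length and may miss streamlines with unusually long
segments. `complete` is the default. The result records instrumentation
counters (points touched per phase, segment tests) so the interactive-scale
contract — phase 1 touches only points in the ROI AABB, phase 2 only points
in the inflated box — is testable.

## Tractometry

`traverse_segment` is an Amanatides–Woo march over the voxel grid: the
segment is first clipped to the grid box (Liang–Barsky), entry/exit voxels
are floored (with an exact-upper-boundary clamp), and the march steps the
axis with the smallest next-crossing parameter. When two crossing
parameters tie exactly (a corner/edge contact) axes step in fixed x→y→z
order, producing the intermediate voxel deterministically; the loop is
bounded by the Manhattan distance between entry and exit voxels, which also
makes it robust to float ties. Out-of-grid geometry contributes nothing
(out-of-grid *points* are counted in a warning).

Voxel weights support two weightings:

* `per_streamline` (default): each streamline adds 1 to every voxel of its
  voxel set. This is the only weighting under which the segment-based
  weighted mean is invariant to resampling of identical geometry — the
  stated goal of compression-robust tractometry — and it is what makes the
  segment-based difference map of a losslessly re-sampled bundle exactly
  zero.
* `per_sample`: +1 per point in the voxel (point mode) or per segment-voxel
  incidence (segment mode). This reproduces the biased baseline whose
  weight loss under compression concentrates in straight, densely sampled
  regions.

`bundle_summary` reports the binary mean (each traversed voxel once), the
weighted mean, the traversed-voxel count and volume = count × voxel volume
(mode-dependent by construction). `R(M_c) = |M_c − M_0| / |M_0|` is
computed from the weighted mean by default (a flag selects the binary
mean).

## Synthetic phantoms

The generators stand in for a real single-subject acquisition. Defaults
mirror a typical one: a 50³ grid at 2 mm isotropic and a 0.5 mm tracking
step. Four centerline kinds: straight line, circular arc (radius/angle),
helix (arc-length parametrized, so steps stay uniform), and a unit-speed
random walk whose direction is perturbed each step by a folded-normal angle
(σ = `angular_jitter`) about a uniformly random azimuth in the plane
orthogonal to the current direction — one knob emulating the sharp local
direction changes of probabilistic tracking; zero jitter degenerates
bit-exactly to the straight generator. A bundle rigidly offsets one
centerline per streamline by a uniform-disk sample (radius
`cross_section`) in the plane orthogonal to the initial direction, which
preserves exactly uniform step lengths. Generation is fully seeded
(separate substreams for offsets and walk noise) and raises if any point
leaves the grid.

Analytic metric maps are evaluated at voxel centers: constant,
`axis_gradient` (normalized voxel-center coordinate, `(i+0.5)/dim`), and
`radial` (normalized distance from a stated center). Two canonical scenes:
`cc_like` (arc bundle, radius 20 mm over 120°, 50 streamlines, 5 mm cubic
ROI at the apex) and `cst_like` (straight 60 mm bundle, same ROI midway).
The ROI sits at a generic position 4.1 mm off the exact midpoint so that
outcomes never hinge on accidental alignment between the box and the
sampling or post-compression keeping lattice — with round defaults an
exactly-midpoint box can land precisely on a kept point of the collinear
bundle, a measure-zero coincidence a real ROI placement would not exhibit.

What the phantoms do *not* emulate: crossing/kissing fiber configurations,
partial-volume and noise effects in the metric maps, anatomically realistic
bundle shapes, or tracking-algorithm step-size adaptivity. Tests passing on
phantoms demonstrate the geometric correctness and compression-robustness
contracts of the algorithms, not anatomical fidelity.

## Test problem sizes and numerical checks

The test suite exercises: a 200-streamline phantom suite (4 kinds × 50)
across `met ∈ {0, 0.1, 0.2, 0.5}` × `mld ∈ {5, 10, ∞}` for the
linearization bounds; 50 random (phantom, ROI) pairs — boxes and ellipsoids
of random size and orientation, compressed and uncompressed — for selection
exactness against brute force; 10⁴ generic-position random segments against
a 10⁴-point supersampling oracle for the traversal (segments are
rejection-sampled so consecutive plane-crossing parameters are ≥ 2e-4
apart, which guarantees the 1e-4-spaced sampling grid hits every traversed
voxel — the oracle check is then exact, not probabilistic); and the
tractometry bias ordering on the curved scene over 20 seeds with a majority
vote (at thresholds where both deviations approach machine epsilon the
ordering is vacuous noise; the vote absorbs it). The robustness experiment
compresses with unconstrained MLD so the measured effect is purely the
error threshold's.
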