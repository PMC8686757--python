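# Methods

## The model: Cones of Sight from close-packed spheres

The package answers "what is next to this object, in which direction, and
how far?" for scenes of labelled 3D point sets.  Around a chosen *central
object* the space is partitioned into 12 solid cones ("Cones of Sight"),
one per nearest-neighbour direction of the cubic close packing (CCP/FCC)
sphere arrangement — the densest packing of equal spheres, in which every
sphere touches 12 equidistant neighbours (packing density π/(3√2) ≈
0.74048, which the `fcc_packing_density_mc` benchmark recovers by Monte
Carlo).

Each cone is derived from a *generating sphere* `S((a,b,c), R)`: the cone
with vertex at the origin tangent to that sphere, i.e. axis `(a,b,c)/‖(a,b,c)‖`
and half-angle `arcsin(R/‖(a,b,c)‖)`.  The same surface is the zero set of
the quadratic

```
(−2ax − 2by − 2cz)² − 4(x²+y²+z²)(a²+b²+c²−R²) = 0 ,
```

and `≥` selects points on or inside it.  Two deliberate choices:

* **Nappe restriction.**  The quadratic describes a double cone; points
  opposite the generating sphere would satisfy it while lying in the wrong
  direction.  Membership therefore additionally requires `ax+by+cz ≥ 0`.
* **Dual representation.**  Cones are stored as (axis, half-angle); the
  angular test `angle(p, axis) ≤ half-angle` is numerically stable and
  yields a closed-form point-to-cone distance.  The algebraic predicate is
  retained and the test suite verifies exact agreement away from a 1e−9
  boundary band.
* **Boundaries count as inside**, including the vertex, which lies on
  every cone's boundary; deterministic first-match order (below) resolves
  its assignment.

## The canonical family and its coverage

The 12 generating centers are the published coordinates (components from
{0, ±1, ±2, ±0.68, ±1.68}), with intuitive direction labels in fixed
canonical order TL, TF, TR, LF, L, LB, RF, R, RB, BL, BB, BR.  These
coordinates round the exact FCC directions (±1/√3 ≈ 0.577 → 0.68, 2√6/3 ≈
1.633 → 1.68); the rounded values are kept as the canonical default to
reproduce the published geometry, and `build_family12(centers="fcc")`
provides the ideal arrangement (all half-angles exactly 30°).

**Generating-sphere radius.**  The source material never states R.  The
default is R = 1, which makes the spheres at the published centers
near-tangent (center separations 1.955–2.07) and yields half-angles
28.89°–30.76°.  With R = 1 the sum of the cones' spherical-cap fractions
is 0.8050 and the *union* (caps overlap slightly between some neighbour
pairs) is 0.8005 by quadrature — hence initial conification covers just
over 80% of directions, matching the documented "at least 80%" behaviour.
The exact published coverage figures (82.7–83.15%) are not reproducible
without the authors' radius; only the 80%/20% bounds are treated as
claims, and the stronger check is agreement with the cap-union oracle
within Monte-Carlo error.  R is exposed as a parameter; coverage is
monotone in it.

## Conification

1. **Re-center**: translate the scene so the central object's anchor is
   the origin.  The anchor is its centroid by default, its stored anchor
   point (the centromere, for chromosomes whose centroid may lie outside
   the territory), or an explicit point.
2. **Initial conification**: each point gets the *first* cone in canonical
   order whose membership test passes, else stays unassigned.  First-match
   makes overlaps and boundaries deterministic.
3. **Fallback ("full conification")**: each unassigned point is assigned
   to the cone minimising the Euclidean point-to-solid-cone distance
   (closed form: 0 inside; `‖p‖ sin(α−θ)` for `θ < α ≤ θ+π/2`; `‖p‖`
   beyond, where the apex is nearest).  Ties break to the canonically
   first minimiser.  The closed form is validated against constrained
   numerical minimisation over an explicit cone parameterisation.

After full conification every point carries five parameters
(x, y, z, obj_id, cos_id) and each object is partitioned across cones.

## Profiles, rankings, charts

Per (cone, object) pair with at least one point, the profile records the
min and max Euclidean norm of the re-centered coordinates and the fraction
of the object's points in the cone.  Distances are **anchor-based** (norms
from the vertex), not set-to-set distances: this is the reading that makes
the central object's own bars start above zero, and the denominators are
whole-object point counts so fractions sum to 1 per object.  Pairs without
points get no entry (empty subchart slots), and the central object's own
bars are kept.

`nearest_object` / `farthest_object` rank non-central objects by the
minimum over cones of the per-cone minimum distance — the "lowest min bar"
reading — ascending and descending respectively.  Fractions (bar colours)
do not enter the ranking; they are exposed for the user's judgement.

The chart is a 4×3 grid of subcharts (rows TOP/LEFT/RIGHT/BOTTOM) with a
shared distance axis; its default upper limit is the envelope diameter
when the scene has one (e.g. 7.3 µm for the modelled nucleus) or the
global maximum distance otherwise.  Bar colour encodes the fraction decile
through a discrete sequential light-yellow→dark-brown ramp (matplotlib
`YlOrBr`, the ColorBrewer sequential palette); bins are right-closed
`(k/10, (k+1)/10]` because every fraction range conventionally quoted in
chart readings is a decile, so e.g. exactly 10% stays in the lowest bin
and 1.0 in the top one.  Zero-span bars (single-point objects) render as
minimal-height ticks rather than vanishing.  The subchart order within the
grid and the palette are configurable; the defaults are documented here.
Rendering is deterministic (fixed fonts, figure size, SVG hash salt, no
timestamps) so vector output is byte-stable.

## Synthetic data

No public dataset accompanies the method, so the generators in
`dpc12.synthetic` define the study conditions:

* **Uniform ball** (`sample_uniform_ball`): rejection-free radial method,
  `radius · U^{1/3}` times a uniform unit vector.  Used for the coverage
  benchmark; since membership depends only on direction, ball coverage
  equals the cap-union solid angle regardless of radius.
* **Mouse 3D Set** (`make_m3ds`): head radius 2 at the origin; ears of
  radius 1 at offsets 4.2 (left) and 4.83 (right) along the TL/TR cone
  axes — a 15% asymmetry, left ear strictly closer.  The published
  description states the asymmetry in both directions in different
  passages; this package fixes **left-ear-closer** as its convention and
  asserts it consistently.  The 4.2 offset keeps the head, viewed from an
  ear, within the opposite cone's half-angle, so with an ear central the
  other objects occupy only right/bottom-side cones, the opposite ear
  exactly one cone — the qualitative chart readings the fixture exists to
  reproduce.
* **Bead-chain nucleus** (`make_bead_chain_nucleus`): 24 chains (12
  chromosome pairs, labels `1,1',…,12,12'`) of 30 beads at a fixed 0.3 µm
  step inside a 3.65 µm-radius envelope (diameter 7.3 µm, one bead ≈ one
  1 Mb domain), generated by fixed-step random walks with specular
  reflection at the envelope (step length exact to 1e−9); the middle bead
  is the centromere anchor; plus a central nucleolus ball (radius 0.8 µm,
  300 points).  This emulates the *shape* of modelled territory data —
  compact-ish labelled point chains in a nucleus — not any particular
  model instance: chains are not self-avoiding, do not interact, and no
  published per-chromosome distances are targeted.  Passing tests
  therefore demonstrate the machinery on territory-like geometry, not
  biological realism.
* **FCC unit cell** (`fcc_packing_density_mc`): cube of side 2√2 with
  spheres at 8 corners and 6 face centers; sphere parts protruding out of
  the cell are exactly compensated by neighbouring cells' spheres
  protruding in, so the uniform-sample hit fraction estimates the packing
  density.

All generators are deterministic given their seed.

## Numerical choices and problem sizes

* Membership comparisons are exact `≥` on floats; the equivalence test
  tolerates a 1e−9 angular boundary band.
* Profile fractions sum to 1 within 1e−9 by construction (integer counts).
* Scene/assignment CSVs are written at 10 significant digits; profile
  CSVs at 17 (lossless round-trip, with `float_precision="round_trip"` on
  read).
* The coverage benchmark runs at 10⁶ points (about a second, vectorised);
  unit tests use 10⁴–10⁵ points and compare against the quadrature oracle
  rather than asserting the 80% bound at scales where sampling noise
  exceeds the ~0.05 percentage-point margin of the true value (80.055%).

## Known limitations

* Only the 12-cone CCP family is provided (no octant or subdivided
  families); cone vertices are always the re-centered origin.
* `farthest_object` ignores fractions; two objects with nearly equal min
  distances but very different concentrations are ranked by distance only.
* No readers for microscopy formats; scenes enter as delimited text.
* The bead-chain generator is a geometric emulation, not a chromatin
  model.
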