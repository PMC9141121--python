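# Methods

## Model overview

The pipeline treats an orthodontic archwire as a slender linear-elastic beam
and the force it exerts on each bracket as a one-dimensional spring law
`F = k(y) · xⁿ`, where `y` (mm) is the curvilinear (arc-length) coordinate
of the bracket site on the wire, `x` (mm) is the deformation of the wire at
that site between its undeformed and deformed (ligated) states, and `k`
(N/mm) is a position-dependent elastic constant. `n = 1` for metallic wires;
`n ∈ {2, 3}` is supported for non-metallic wires but untested against
reference data. The resulting per-bracket forces are applied to a
linear-elastic model of teeth and alveolar bone.

## Wire geometry (arch_geometry)

Arch curves are half-superellipses `|X/a|^m + |Y/b|^m = 1` (width `2a`,
depth `b`, flatness `m ≥ 1`; `m = 2` with `b = a` gives a semicircle),
optionally tilted out of the occlusal plane, resampled to uniform arc length
and scaled isotropically so the polyline length equals the requested total
length exactly. This family was chosen because only lengths and arc-length
coordinates matter downstream; the true patient spline is unrecoverable.
All curves are polylines with ≥ 1000 samples; coordinates are millimetres.

Two station coordinates are used. The curvilinear coordinate `y` is the
cumulative arc length from the wire start to the orthogonal projection of a
point; the chord coordinate `z` is the straight-line distance from the wire
start to that projection. `z ≤ y` always, with equality on straight wires.
The projection tolerance defaults to 0.5 mm (configurable). In the
end-to-end pipeline, per-tooth `y` is measured from the distal end of the
hemiarch containing the site along the deformed centerline
(`y = min(s, L − s)`), so contralateral molars receive near-equal
coordinates; this convention is this package's choice — the source
measurement convention is ambiguous (its `y` values run past the trimmed
half-length).

Deformed wires are built by prescribing 3D offsets at bracket sites and
interpolating the displacement field along arc length with a natural cubic
spline pinned to zero at both wire ends. Injected offsets are recovered by
`measure_deformation` within 2% (resampling error).

## Beam virtual laboratory (beam_fem)

The wire (circular section, default diameter 0.3556 mm = 0.014 in) is
discretized into 2-node space-frame elements — axial `EA`, torsion `GJ`,
and two-plane Euler–Bernoulli bending `EI`, 12 DOF per element — with both
end nodes fully clamped. Element local axes take `x` along the chord and a
global-Z reference vector for the bending planes (falling back to global Y
near-vertical chords). The reduced stiffness matrix is symmetric positive
definite and factorized once (dense Cholesky; models stay below ~3000 DOF at
the default 1 mm element length), so force sweeps cost one triangular solve
per load case.

Solid tetrahedra would also work for this geometry, but a frame model
reproduces the same linear physics at a fraction of the cost for a beam
whose length/diameter ratio is ~300, and Hermite elements are nodally exact
for point loads — the closed forms `x = FL³/(192EI)` (clamped-clamped
center load) and `x = Fa³b³/(3EIL³)` (off-center) hold to ~1e-13 relative
and anchor the test suite. Small-displacement theory is used throughout even
though calibration sweeps at 10 N produce deflections comparable to the wire
length; the reference load-deflection tables are themselves exactly linear,
so a geometrically nonlinear solver would not reproduce them.

Material presets (nitinol wire, Ni+Cr brackets, bone, enamel) ship as JSON
with the published values. Two caveats are stored with the data rather than
corrected: the nitinol Young's modulus (8.3 × 10⁷ Pa) is about three orders
of magnitude below handbook NiTi but is internally consistent with the
published shear modulus and deflections, so it is used as given; and the
bone transverse modulus differs from `E/(2(1+ν))` by ~0.6% (each preset
records its isotropy mismatch).

## Calibration and the sextic fit (stiffness_calibration, force_law)

The calibration protocol sweeps forces `{0.1 … 10} N` at chord stations
`z ∈ {10, 20, 30, 40, 50} mm` plus the wire middle (half the trimmed arc
length), records `k = F/x`, and verifies force-invariance (relative spread
< 1e-9 for solver output; 1e-4 for the bundled printed tables, whose 5-digit
rounding introduces ~1e-5 spread at the wire-middle station). Each station
contributes one `(y, k)` node (the smallest-force record); the node `(0, 0)`
is prepended, fixing the constant term of the polynomial at zero.

The degree-6 interpolant through the seven nodes is found by solving the
6×6 monomial Vandermonde system for `(a, b, c, d, e, f)`. At stations up to
y ≈ 60 mm the condition number is ~5×10¹⁰, so the solve uses pivoted LU with
one iterative-refinement step whose residual is accumulated with `math.fsum`;
this recovers the published coefficients to ~8 significant figures, and an
independent barycentric-interpolation oracle agrees to 1e-6 relative in the
tests. Fits whose condition number exceeds 1e12 emit an audit warning.
Node sets without a zero node are handled by fitting `g` as a seventh
unknown. Evaluation uses Horner's scheme; `y` beyond the last node emits an
extrapolation warning because a sextic diverges quickly outside its span
(per-tooth coordinates run to 73.11 mm, well past the last node at 59 mm,
and the largest published forces are extrapolations). Between nodes the
interpolant can be negative; signed values are returned and magnitudes
reported per tooth.

### Source-data inconsistencies (surfaced, not patched)

* The bundled node table carries two stiffness values at `y = 20.04` that
  differ by exactly 10× (0.047418 from the sweep, 0.004741799 in the
  interpolation system). The fit follows the interpolation system, whose
  published coefficients are consistent with the smaller value; the audit
  reports the conflict.
* Of the two published coefficient sets ("upper" and "lower" wires), the
  "upper" set regenerates the published per-tooth force tables of *both*
  arches (22/22 rows within 1%, median row error ~1e-6), while the "lower"
  set regenerates almost none (2/22). The labels appear swapped at the
  force-table stage of the source. `published_law(arch, validated=True)`
  therefore routes both arches to the "upper" set and records the mapping;
  `validated=False` returns the sets as labeled.

## Per-tooth forces (tooth_forces)

Forces are reported as magnitudes `|k(y)·xⁿ|` with unit direction vectors
from the bracket guide-point plane normals (directions are set graphically
in clinical FE workflows; the plane normal is the closest programmatic
analog). FDI codes are strings, validated against arch membership
(quadrants 1–2 upper, 3–4 lower). The summary counts entries above 1 N —
the level commonly cited as the upper bound of optimal orthodontic force —
as information, not as a filter: the bundled case itself has two brackets
above 1 N (11.88 N and 4.45 N, both extrapolations beyond the calibration
span, on the upper central incisors).

## Tissue response (tissue_fem)

Patient geometry is unavailable, so the final stage runs on a parameterized
synthetic segment: a rectangular bone block (default 36 × 14 × 20 mm) with
frustum-shaped teeth (crown radius 3.5 mm tapering to 1.6 mm over a 12 mm
root) and 4 mm square bracket pads bonded on the buccal face. The mesh is a
structured hexahedral grid split into six tetrahedra per cell (Kuhn
triangulation, conforming and watertight by construction; ~7500 tets at the
default density), with region labels assigned per element centroid
(priority bracket > tooth > bone) and a seeded jitter of interior nodes
(≤ 12% of the cell size) that preserves a quality floor (normalized radius
ratio > 0.2). Materials default to the published presets (enamel teeth,
bone block, Ni+Cr pads).

The solver is standard tet4 linear elasticity (mm-N-MPa internally). Pad
forces are applied as consistent uniform tractions over the pad's boundary
triangles (falling back to equal nodal shares when the mesh is too coarse
to contain whole pad triangles); the bottom face of the block is fixed.
Outputs are nodal displacements (mm), per-element strain, von Mises stress
(Pa) and strain energy (J), with field maxima and locations, exported as
legacy ASCII VTK plus a maxima table. Verification: constant-strain patch
test to machine precision, uniaxial bar against `FL/(EA)` and `F/A` within
2%, global equilibrium and the energy identity `U = ½uᵀf` to 1e-8 relative,
and monotone error decay under refinement. Because the geometry is
synthetic, the absolute magnitudes of the published patient maps are out of
scope; the module demonstrates the same pipeline stage with verifiable
physics. The "strain" map reports the largest absolute normal strain
component per element and the stress map the von Mises equivalent — the
conventional FE post-processing defaults.

## Pipeline defaults and problem sizes

The end-to-end synthetic run uses a 2001-sample wire at the published
lengths (152.12 mm generated, trimmed to 109.68 mm), 1 mm beam elements
(~660 DOF), the published station/force grids (66 load cases, one
factorization), per-tooth offsets drawn uniformly from 1–9 mm (the range of
the published deformations) at ten bracket sites, and a (18, 7, 10)-cell
tissue grid. A full run takes about a second on a laptop-class CPU; all
randomness flows from a single integer seed and reruns are checksum
identical.

## Known limitations

* No wire–bracket contact, friction, or slot clearance: the deformation `x`
  is prescribed, not solved from ligation mechanics.
* Nitinol superelasticity (phase transformation, hysteresis) is not
  modeled; the wire is linear isotropic, consistent with the calibration
  data but not with large real deflections.
* The sextic force law is an exact interpolant, not a regression — it
  oscillates between nodes and explodes beyond them; extrapolated teeth are
  flagged but still reported, matching the reference workflow.
* Tet4 elements are stiff in bending; tissue results converge from below
  and the mesh density is the accuracy knob.
* No periodontal ligament, bone remodeling, or time-dependent tooth
  movement: forces are instantaneous elastic reactions.
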