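# orthowire

Force modeling for fixed orthodontic appliances. During straight-wire
treatment a superelastic archwire, forced into the displaced bracket slots of
malpositioned teeth, exerts a restoring force on every bracket as it returns
toward its undeformed shape. `orthowire` implements the full chain from wire
geometry to tissue response:

1. **Stiffness calibration.** A clamped archwire behaves locally like a
   spring: a point force *F* at a station produces a deflection *x* with
   *F = k·x*, where the elastic constant *k* depends on where along the wire
   the force acts. A 3D space-frame beam solver (axial + torsion + biaxial
   Euler–Bernoulli bending, both ends clamped) serves as the virtual
   laboratory: forces from 0.1 to 10 N are swept over stations and *k = F/x*
   is tabulated. Linearity makes *k* exactly force-independent, which the
   calibration verifies.
2. **Sextic force law.** With seven calibration nodes *(yᵢ, kᵢ)* — *y* the
   curvilinear (arc-length) coordinate, including the implicit *(0, 0)* at
   the clamp — the position dependence is modeled as an interpolating
   degree-6 polynomial

       k(y) = a·y⁶ + b·y⁵ + c·y⁴ + d·y³ + e·y² + f·y + g,   g = 0,

   whose coefficients solve a 6×6 Vandermonde-type linear system (solved
   with pivoted LU plus iterative refinement; the system's condition number
   is ~10¹⁰).
3. **Per-tooth forces.** For each bracket (FDI tooth code) the measured wire
   coordinate *y* and deformation *x* give the force magnitude
   *F = |k(y)·xⁿ|* (*n* = 1 for metallic wires), with direction taken from
   the bracket's guide-point plane.
4. **Tissue response.** The bracket forces load a linear-elastic tet4 finite
   element model of a (synthetic) tooth-in-bone segment, producing
   displacement, strain, von Mises stress and strain-energy maps with their
   maxima.

The package bundles the published calibration tables of a real treated case
(0.014-inch nitinol wires, upper wire 152.12 mm trimmed to 109.68 mm) as
plain-text fixtures, and a synthetic-arch generator for end-to-end runs when
no patient geometry is available.

## Worked example

```python
from orthowire import fit_sextic, evaluate_k, evaluate_force
from orthowire.stiffness_calibration import load_published_nodes

nodes = load_published_nodes()   # seven (y, k) nodes, (0.0, 0.0) first
law = fit_sextic(nodes, arch="upper")
print(law.f)                     # 0.1427732052368317   (N/mm per mm)
print(evaluate_k(law, 10.0))     # 0.23623900000000003  (N/mm)
print(abs(evaluate_force(law, x=1.31, y=28.65)))  # 0.01764800932127615 (N)
```

The linear coefficient `f` and the spot value `k(10) = 0.236239 N/mm` match
the published fit to ~8 significant figures; the last line is the elastic
force (N) on a first molar whose bracket sits at arc coordinate 28.65 mm
with a measured wire deformation of 1.31 mm.

A full synthetic pipeline run (arch generation → calibration sweep → fit →
per-tooth forces → tissue maps):

```sh
orthowire run --outdir out --seed 0
orthowire reproduce-published      # audit against the bundled tables
```

`reproduce-published` prints one pass/fail row per published value and
surfaces two internal inconsistencies of the source tables (a tenfold
stiffness conflict at y = 20.04 mm and a swapped arch labeling of the two
published coefficient sets) without patching them.

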