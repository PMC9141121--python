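# Bundled reference data

Small plain-text fixtures transcribed from the published study of the
orthodontic system this package models (a 13-year-old patient treated with
0.014-inch nitinol archwires, straight-wire technique). They are inputs to
the pipeline, not outputs of this package.

- `materials.json` — isotropic (E, G, nu, rho) presets for nitinol, Ni+Cr,
  bone and enamel, as published, with isotropy-consistency notes.
- `load_sweeps_upper.csv` — virtual load–deflection sweeps on the clamped
  upper wire: force F (N), measured deflection x (mm) and the constant
  k = F/x (N/mm) at stations z = 10, 20 and 51.38 mm.
- `calibration_nodes_upper.csv` — the (y, z, k) calibration node table for
  the upper wire, including the implicit (0, 0) node. `K_sweep` is the value
  carried over from the sweeps; `k_y` is the value actually used in the
  published interpolation system. At y = 20.04 the two differ by a factor of
  10 (a transcription inconsistency in the source, surfaced by the audit).
- `tooth_measurements.csv` — per-tooth (FDI code) curvilinear coordinate y,
  measured deformation x, and the published elastic force, both arches.
- `published_laws.json` — the two published sextic coefficient sets and a
  record of which set actually regenerates the published force tables.
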