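{
  "_comment": "Isotropic material presets as published for the modeled orthodontic system. G values are the published transverse moduli; `isotropy_note` records how closely G matches E/(2(1+nu)). The nitinol modulus is the published value, orders of magnitude below handbook NiTi; it is internally consistent with the published deflections and G (see docs/methods.md).",
  "nitinol": {
    "name": "Nitinol archwire",
    "density_kg_m3": 6450.0,
    "youngs_modulus_Pa": 8.3e7,
    "shear_modulus_Pa": 3.12e7,
    "poisson_ratio": 0.33,
    "isotropy_note": "E/(2(1+nu)) = 3.120e7 Pa; matches printed G to 3 s.f."
  },
  "nicr": {
    "name": "Ni+Cr alloy (brackets and tubes)",
    "density_kg_m3": 8500.0,
    "youngs_modulus_Pa": 2.1e11,
    "shear_modulus_Pa": 8.015e10,
    "poisson_ratio": 0.31,
    "isotropy_note": "E/(2(1+nu)) = 8.0153e10 Pa; matches printed G to 4 s.f."
  },
  "bone": {
    "name": "Bone (maxilla, mandible)",
    "density_kg_m3": 1400.0,
    "youngs_modulus_Pa": 1.0e10,
    "shear_modulus_Pa": 3.84e9,
    "poisson_ratio": 0.31,
    "isotropy_note": "E/(2(1+nu)) = 3.817e9 Pa; printed G differs by ~0.6% (kept as printed)."
  },
  "enamel": {
    "name": "Tooth enamel",
    "density_kg_m3": 2958.0,
    "youngs_modulus_Pa": 7.79e10,
    "shear_modulus_Pa": 2.996e10,
    "poisson_ratio": 0.3,
    "isotropy_note": "E/(2(1+nu)) = 2.996e10 Pa; matches printed G to 4 s.f."
  }
}
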