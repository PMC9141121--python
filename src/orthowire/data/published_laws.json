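{
  "_comment": "Published degree-6 elastic-constant coefficient sets, highest power first, g last (units: k in N/mm, y in mm). As published, 'upper' and 'lower' name the two archwires; brute-force evaluation shows the 'upper' set regenerates the published force tables for BOTH arches (median row error ~1e-6), while the 'lower' set regenerates neither (errors up to 17x) — an apparent label swap in the source. validated_for records which set this package uses per arch.",
  "upper": [-1.89309451393284e-09, 3.87447065552008e-07, -3.05120626818607e-05,
            1.15143861398714e-03, -2.07466264631038e-02, 1.42773204710058e-01, 0.0],
  "lower": [-1.40083194030139e-09, 3.04238736235189e-07, -2.54032635123737e-05,
            1.02066672881550e-03, -1.97861695057057e-02, 1.49264732878305e-01, 0.0],
  "validated_for": {"upper": "upper", "lower": "upper"}
}
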