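# Literature relaxation times (3 T, healthy brain, ms) and tissue water
# content used for absolute quantification. All values are editable defaults;
# override any entry through the run configuration.
water_content_mM:          # water concentration per tissue compartment
  WM: 36080.0              # 0.65 * 55510 mM (pure water)
  GM: 43300.0              # 0.78 * 55510 mM
  CSF: 53840.0             # 0.97 * 55510 mM
water_relaxation_ms:
  WM: {T1: 832.0, T2: 79.2}
  GM: {T1: 1331.0, T2: 110.0}
  CSF: {T1: 3817.0, T2: 503.0}
metabolite_relaxation_ms:  # singlet/backbone averages; generic fallback below
  NAA: {T1: 1350.0, T2: 263.0}
  NAAG: {T1: 1350.0, T2: 263.0}
  Cr: {T1: 1240.0, T2: 152.0}
  Cho: {T1: 1100.0, T2: 207.0}
  GPC: {T1: 1100.0, T2: 207.0}
  Glu: {T1: 1270.0, T2: 180.0}
  Gln: {T1: 1270.0, T2: 180.0}
  mI: {T1: 1010.0, T2: 196.0}
  Lac: {T1: 1500.0, T2: 240.0}
default_metabolite_relaxation_ms: {T1: 1300.0, T2: 200.0}
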