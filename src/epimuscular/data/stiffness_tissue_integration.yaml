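# Calibration-derived piecewise stiffness, tissue-integrating mesh group
# (TI, enhanced scar-like intermuscular connectivity).  Sign convention as
# in stiffness_control.yaml: NV2 opposes INT and NV1.
group: TI
c: 0.9
pathways:
  INT:
    breakpoints_mm: [0.0, 1.0, 2.0, 3.0]
    K_mN_per_mm: [549.7, 842.5, 681.1]
  NV1:
    breakpoints_mm: [0.0, 1.0, 2.0, 3.0]
    K_mN_per_mm: [19.9, 45.7, 29.6]
  NV2:
    breakpoints_mm: [0.0, 1.0, 2.0, 3.0]
    K_mN_per_mm: [-69.4, -5.6, -35.5]
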