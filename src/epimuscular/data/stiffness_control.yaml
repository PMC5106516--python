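# Calibration-derived piecewise stiffness, normal-connectivity group (NO).
# Values are signed: positive segments reroute force toward the proximal
# LG+PL tendon; the NV2 neurovascular tract transmits in the opposite
# direction to INT and NV1 and therefore carries negative values.
# Segment j covers the displacement-magnitude band
# [breakpoints_mm[j], breakpoints_mm[j+1]]; negative positions use odd
# symmetry.
group: "NO"
c: 0.9
pathways:
  INT:
    breakpoints_mm: [0.0, 1.0, 2.0, 3.0]
    K_mN_per_mm: [239.8, 171.7, 143.9]
  NV1:
    breakpoints_mm: [0.0, 1.0, 2.0, 3.0]
    K_mN_per_mm: [21.7, 0.4, 34.6]
  NV2:
    breakpoints_mm: [0.0, 1.0, 2.0, 3.0]
    K_mN_per_mm: [-56.6, -30.8, -17.1]
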