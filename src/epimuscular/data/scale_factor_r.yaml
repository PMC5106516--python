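# Per-segment ratio r of intermuscularly transmitted force under
# proximal-only repositioning versus proximal-plus-distal repositioning,
# estimated from the distal-only-resection subset (n = 3, normal
# connectivity).  Segment j covers [breakpoints_mm[j], breakpoints_mm[j+1]].
breakpoints_mm: [0.0, 1.0, 2.0, 3.0]
r: [0.07, 0.13, 0.21]
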