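# Directional 8-contact lead, dimensions in mm, conductivities in S/m.
contact_height: 1.5
radius: 0.635
spacing: 1.5
rows: [ring, segmented, segmented, ring]
segment_arc_deg: 100.0
segment_gap_deg: 20.0
shaft_length: 60.0
shaft_sigma: 0.0
contact_sigma: 4.0e+6
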