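# Conserved-histidine motif of the fatty acid hydroxylase superfamily:
# nine histidines coordinating the bimetal active-site center.
# Positions are 1-based coordinates in the synthetic stand-in reference.
reference_id: "PtAltSQE"
required_residue: "H"
positions: [88, 92, 105, 109, 110, 201, 205, 294, 298]
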