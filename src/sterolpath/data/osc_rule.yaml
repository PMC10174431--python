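# Oxidosqualene-cyclase product-specificity rule.
# Sites are 1-based positions in the coordinate system of the reference
# sequence below (a synthetic stand-in numbered like the human enzyme).
# Each class lists the accepted residues per site, in site order.
reference_id: "hsa:4047"
sites: [381, 449, 453]
classes:
  cycloartenol_synthase: ["Y", "H", "I"]
  lanosterol_synthase: ["T", "CQ", "V"]
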