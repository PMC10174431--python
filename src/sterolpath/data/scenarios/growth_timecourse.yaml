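# Untreated fermentation timecourse. End sterols (cholesterol,
# stigmasterol) dip at 48 h and peak at 72 h; the cyclase products
# (lanosterol, cycloartenol) peak at 48 h and decline by 72 h.
# The 72-h values are the reported endpoint concentrations (mg/g DCW);
# the 24/48-h values are plausible fills with the observed shape.
name: growth_timecourse
inhibitor: none
times_h: [24, 48, 72]
concentrations: []
baselines:
  cholesterol: {24: 0.38, 48: 0.30, 72: 0.55}
  stigmasterol: {24: 0.85, 48: 0.62, 72: 1.17}
  lanosterol: {24: 1.20, 48: 3.10, 72: 2.47}
  cycloartenol: {24: 1.35, 48: 3.40, 72: 2.66}
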