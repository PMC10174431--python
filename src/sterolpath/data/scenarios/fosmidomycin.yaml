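# DXR inhibition (fosmidomycin). The organism lacks the plastidial MEP
# route, so the inhibitor has no effect even at 100 uM: every planted
# multiplier is 1.0 and no contrast should reach significance.
name: fosmidomycin
inhibitor: fosmidomycin
times_h: [48]
concentrations: [20, 50, 100]
baselines:
  cholesterol: {48: 0.30}
  stigmasterol: {48: 0.62}
  lanosterol: {48: 3.10}
  cycloartenol: {48: 3.40}
  squalene: {48: 1.50}
  beta-carotene: {48: 0.20}
multipliers:
  cholesterol: {20: 1.0, 50: 1.0, 100: 1.0}
  stigmasterol: {20: 1.0, 50: 1.0, 100: 1.0}
  lanosterol: {20: 1.0, 50: 1.0, 100: 1.0}
  cycloartenol: {20: 1.0, 50: 1.0, 100: 1.0}
  squalene: {20: 1.0, 50: 1.0, 100: 1.0}
  beta-carotene: {20: 1.0, 50: 1.0, 100: 1.0}
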