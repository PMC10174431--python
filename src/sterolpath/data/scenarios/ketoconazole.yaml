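# Sterol 14-alpha-demethylase inhibition (ketoconazole) at 48 h. Planted
# 2 uM multipliers reproduce the reported effects: squalene -51.36%,
# lanosterol -90.60%, cholesterol +80.76%, beta-carotene -51.01%;
# stigmasterol is completely blocked (undetectable) at every dose.
name: ketoconazole
inhibitor: ketoconazole
times_h: [48]
concentrations: [0.5, 1, 2]
baselines:
  cholesterol: {48: 0.30}
  stigmasterol: {48: 0.62}
  lanosterol: {48: 3.10}
  squalene: {48: 1.50}
  beta-carotene: {48: 0.20}
multipliers:
  squalene: {0.5: 0.85, 1: 0.70, 2: 0.4864}
  lanosterol: {0.5: 0.60, 1: 0.30, 2: 0.0940}
  cholesterol: {0.5: 1.20, 1: 1.50, 2: 1.8076}
  stigmasterol: {0.5: 0.0, 1: 0.0, 2: 0.0}
  beta-carotene: {0.5: 0.80, 1: 0.65, 2: 0.4899}
qpcr_conc_uM: 2
qpcr_times_h: [48]
qpcr_log2fc:
  HMGR: {48: -1.40}
  OSC: {48: -1.10}
  CYP51G1: {48: -1.70}
  crtIBY: {48: -1.20}
  pfaA: {48: -0.90}
  pfaB: {48: -0.80}
  pfaC: {48: 0.70}
  FAS: {48: 0.10}
  ACC: {48: -0.10}
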