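# HMGR inhibition (mevinolin) at 48 h of treatment. Planted multipliers at
# 100 uM reproduce the reported endpoint effects: beta-carotene -64.69%,
# squalene -93.70%, cholesterol 4.51-fold, stigmasterol 2.39-fold; fatty
# acid fractions at 50 uM: TFA +15.24%, PUFA +27.44%, SFA +7.68%.
# Intermediate-concentration cells without a reported value are plausible
# monotone fills; lanosterol is undetectable at 100 uM.
name: mevinolin
inhibitor: mevinolin
times_h: [48]
concentrations: [20, 50, 100]
baselines:
  cholesterol: {48: 0.30}
  stigmasterol: {48: 0.62}
  lanosterol: {48: 3.10}
  cycloartenol: {48: 3.40}
  squalene: {48: 1.50}
  beta-carotene: {48: 0.20}
  TFA: {48: 450.0}
  SFA: {48: 200.0}
  PUFA: {48: 220.0}
multipliers:
  cholesterol: {20: 1.60, 50: 2.80, 100: 4.51}
  stigmasterol: {20: 1.30, 50: 1.80, 100: 2.39}
  lanosterol: {20: 0.80, 50: 0.45, 100: 0.0}
  cycloartenol: {20: 0.85, 50: 0.55, 100: 0.30}
  squalene: {20: 0.70, 50: 0.35, 100: 0.063}
  beta-carotene: {20: 0.80, 50: 0.60, 100: 0.3531}
  TFA: {20: 1.08, 50: 1.1524, 100: 0.90}
  SFA: {20: 1.03, 50: 1.0768, 100: 0.92}
  PUFA: {20: 1.10, 50: 1.2744, 100: 0.88}
qpcr_conc_uM: 50
qpcr_times_h: [12, 24, 48]
qpcr_log2fc:
  ACAT: {12: -0.30, 24: -1.20, 48: -1.60}
  HMGS: {12: 0.40, 24: 0.90, 48: 1.20}
  HMGR: {12: -0.50, 24: -1.50, 48: -2.00}
  MK: {12: -0.20, 24: -0.80, 48: -1.10}
  PMK: {12: -0.30, 24: -0.90, 48: -1.30}
  MPDC: {12: 0.30, 24: 0.80, 48: 1.10}
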