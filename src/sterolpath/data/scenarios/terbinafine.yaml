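# Squalene-epoxidase inhibition (terbinafine) at 48 h. Squalene and the
# cyclase products fall concentration-dependently; cholesterol doubles at
# 100 uM while lanosterol becomes undetectable; beta-carotene multipliers
# at 20/50/100 uM reproduce the reported -7.85% / -30.27% / -37.61%; fatty
# acid fractions at 50 uM: TFA +6.23%, SFA +12.42%, PUFA +7.99%.
name: terbinafine
inhibitor: terbinafine
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
  squalene: {20: 0.65, 50: 0.35, 100: 0.12}
  lanosterol: {20: 0.75, 50: 0.40, 100: 0.0}
  cycloartenol: {20: 0.80, 50: 0.50, 100: 0.25}
  cholesterol: {20: 1.05, 50: 1.10, 100: 2.00}
  stigmasterol: {20: 1.02, 50: 1.05, 100: 0.85}
  beta-carotene: {20: 0.9215, 50: 0.6973, 100: 0.6239}
  TFA: {20: 1.03, 50: 1.0623, 100: 0.95}
  SFA: {20: 1.05, 50: 1.1242, 100: 0.97}
  PUFA: {20: 1.04, 50: 1.0799, 100: 0.94}
qpcr_conc_uM: 50
qpcr_times_h: [48]
qpcr_log2fc:
  SQS: {48: 1.30}
  AltSQE: {48: 1.60}
  OSC: {48: 1.10}
  CYP51G1: {48: 1.40}
  HMGR: {48: 0.15}
  FAS: {48: 0.90}
  pfaA: {48: 0.10}
  pfaB: {48: -0.10}
  pfaC: {48: 1.00}
  ACC: {48: 0.10}
  crtIBY: {48: -0.80}
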