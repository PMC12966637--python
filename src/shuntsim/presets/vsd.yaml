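# Isolated ventricular septal defect scenario (baseline column).
# Timings are fractions of the heartbeat period; relaxation onset is
# contraction onset + contraction duration.
name: vsd
thb: 0.8
chambers:
  la: {ea: 0.2273, eb: 0.209, tc_frac: 0.79, dc_frac: 0.11, dr_frac: 0.8}
  lv: {ea: 3.0391, eb: 0.10, tc_frac: 0.0, dc_frac: 0.35, dr_frac: 0.4}
  ra: {ea: 0.0429, eb: 0.0636, tc_frac: 0.8, dc_frac: 0.1, dr_frac: 0.7}
  rv: {ea: 0.6683, eb: 0.07, tc_frac: 0.0, dc_frac: 0.3, dr_frac: 0.4}
valves: {rmin: 0.0075, rmax: 75006.2}
shunts: {rasd: closed, rvsd: 0.038}
compartments:
  arsys: {r: 0.588, c: 0.96, l: 5.0e-3}
  vensys: {r: 0.352, c: 60.0, l: 5.0e-4}
  arpul: {r: 0.104, c: 5.0, l: 5.0e-4}
  venpul: {r: 0.0105, c: 16.0, l: 5.0e-4}
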