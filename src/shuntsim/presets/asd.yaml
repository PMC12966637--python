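# Isolated atrial septal defect scenario. The ventricular passive
# elastances and vascular resistances encode a remodelled baseline; the
# static pulmonary resistive sum of this column is about 5 Wood units
# (see the sweep engine's PVR normalization).
name: asd
thb: 0.8
chambers:
  la: {ea: 0.2273, eb: 0.209, tc_frac: 0.79, dc_frac: 0.11, dr_frac: 0.8}
  lv: {ea: 2.44, eb: 0.018, tc_frac: 0.0, dc_frac: 0.35, dr_frac: 0.4}
  ra: {ea: 0.0429, eb: 0.0636, tc_frac: 0.8, dc_frac: 0.1, dr_frac: 0.7}
  rv: {ea: 0.6683, eb: 0.0088, tc_frac: 0.0, dc_frac: 0.3, dr_frac: 0.4}
valves: {rmin: 0.0075, rmax: 75006.2}
shunts: {rasd: 0.0031, rvsd: closed}
compartments:
  arsys: {r: 0.699, c: 0.671, l: 5.0e-3}
  vensys: {r: 0.66, c: 60.0, l: 5.0e-4}
  arpul: {r: 0.29, c: 5.0, l: 5.0e-4}
  venpul: {r: 0.0105, c: 16.0, l: 5.0e-4}
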