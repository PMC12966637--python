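parameter,vsd,asd,asd_vsd
EALA,0.2273,0.2273,0.2273
EBLA,0.209,0.209,0.209
EALV,3.0391,2.44,3.0391
EBLV,0.10,0.018,0.10
EARA,0.0429,0.0429,0.0429
EBRA,0.0636,0.0636,0.0636
EARV,0.6683,0.6683,0.6683
EBRV,0.07,0.0088,0.07
Rmin,0.0075,0.0075,0.0075
Rmax,75006.2,75006.2,75006.2
RASD,closed,0.0031,0.0031
RVSD,0.038,closed,0.038
RARSYS,0.588,0.699,0.588
CARSYS,0.96,0.671,0.96
LARSYS,5e-3,5e-3,5e-3
RVENSYS,0.352,0.66,0.352
CVENSYS,60.0,60.0,60.0
LVENSYS,5e-4,5e-4,5e-4
RARPUL,0.104,0.29,0.104
CARPUL,5.0,5.0,5.0
LARPUL,5e-4,5e-4,5e-4
RVENPUL,0.0105,0.0105,0.0105
CVENPUL,16.0,16.0,16.0
LVENPUL,5e-4,5e-4,5e-4
THB,0.8,0.8,0.8
tCLA_frac,0.79,0.79,0.79
TCLA_frac,0.11,0.11,0.11
TRLA_frac,0.8,0.8,0.8
tCLV_frac,0.0,0.0,0.0
TCLV_frac,0.35,0.35,0.35
TRLV_frac,0.4,0.4,0.4
tCRA_frac,0.8,0.8,0.8
TCRA_frac,0.1,0.1,0.1
TRRA_frac,0.7,0.7,0.7
tCRV_frac,0.0,0.0,0.0
TCRV_frac,0.3,0.3,0.3
TRRV_frac,0.4,0.4,0.4
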