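system,site,component,mean,std
MMP-2,,VDWAALS,-31.20,2.71
MMP-2,,EEL,-54.57,6.81
MMP-2,,EPB,73.54,9.17
MMP-2,,ENPOLAR,-23.86,1.24
MMP-2,,EDISPER,41.76,1.39
MMP-2,,DG_GAS,-85.77,7.47
MMP-2,,DG_SOLV,91.43,9.25
MMP-2,,DG_TOTAL,5.67,7.78
MMP-9,,VDWAALS,-30.75,3.45
MMP-9,,EEL,-54.33,6.22
MMP-9,,EPB,66.93,5.29
MMP-9,,ENPOLAR,-24.10,1.67
MMP-9,,EDISPER,42.63,2.91
MMP-9,,DG_GAS,-85.08,6.08
MMP-9,,DG_SOLV,85.46,5.78
MMP-9,,DG_TOTAL,0.39,3.95
HSP90,,VDWAALS,-35.36,2.49
HSP90,,EEL,-6.84,7.37
HSP90,,EPB,34.23,7.73
HSP90,,ENPOLAR,-27.04,1.64
HSP90,,EDISPER,46.83,1.66
HSP90,,DG_GAS,-42.19,7.48
HSP90,,DG_SOLV,54.01,7.59
HSP90,,DG_TOTAL,11.82,6.31
TRPV1,LIG A,VDWAALS,-37.48,3.29
TRPV1,LIG A,EEL,0.02,0.19
TRPV1,LIG A,ENPOLAR,-4.29,0.16
TRPV1,LIG A,DG_GAS,-37.46,3.26
TRPV1,LIG A,DG_SOLV,-4.29,0.16
TRPV1,LIG A,DG_TOTAL,-41.76,3.27
TRPV1,LIG B,VDWAALS,-38.48,2.57
TRPV1,LIG B,EEL,0.94,0.27
TRPV1,LIG B,ENPOLAR,-4.48,0.09
TRPV1,LIG B,DG_GAS,-37.54,2.58
TRPV1,LIG B,DG_SOLV,-4.48,0.09
TRPV1,LIG B,DG_TOTAL,-42.02,2.57
TRPV1,LIG C,VDWAALS,-26.69,1.95
TRPV1,LIG C,EEL,-0.12,0.33
TRPV1,LIG C,ENPOLAR,-3.48,0.20
TRPV1,LIG C,DG_GAS,-26.81,1.92
TRPV1,LIG C,DG_SOLV,-3.48,0.20
TRPV1,LIG C,DG_TOTAL,-30.29,2.03
TRPV1,LIG D,VDWAALS,-48.12,2.99
TRPV1,LIG D,EEL,1.07,0.22
TRPV1,LIG D,ENPOLAR,-4.51,0.12
TRPV1,LIG D,DG_GAS,-47.05,2.98
TRPV1,LIG D,DG_SOLV,-4.51,0.12
TRPV1,LIG D,DG_TOTAL,-51.56,3.00
TRPV1,All Ligs,VDWAALS,-150.77,5.55
TRPV1,All Ligs,EEL,1.90,0.59
TRPV1,All Ligs,ENPOLAR,-16.76,0.33
TRPV1,All Ligs,DG_GAS,-148.87,5.51
TRPV1,All Ligs,DG_SOLV,-16.76,0.33
TRPV1,All Ligs,DG_TOTAL,-165.63,5.55
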