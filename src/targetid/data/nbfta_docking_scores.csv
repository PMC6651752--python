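target,function,fitness,z_score
MMP-2,CHEMPLP,69.81,2.09
MMP-2,GoldScore,31.34,0.57
MMP-2,ChemScore,17.30,1.51
MMP-2,ASP,33.92,1.53
MMP-9,CHEMPLP,83.32,1.38
MMP-9,GoldScore,38.04,0.02
MMP-9,ChemScore,25.99,2.93
MMP-9,ASP,35.29,0.69
HSP90,CHEMPLP,56.67,2.51
HSP90,GoldScore,27.28,0.82
HSP90,ChemScore,11.81,0.82
HSP90,ASP,19.82,-0.55
TRPV1,CHEMPLP,54.05,1.59
TRPV1,GoldScore,25.44,0.57
TRPV1,ChemScore,12.78,0.19
TRPV1,ASP,28.71,3.42
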