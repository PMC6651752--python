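target,function,fitness,z_score
MMP-2,CHEMPLP,99.18,2.71
MMP-2,GoldScore,71.59,2.45
MMP-2,ChemScore,43.01,2.73
MMP-2,ASP,52.24,2.36
MMP-9,CHEMPLP,101.71,1.33
MMP-9,GoldScore,44.64,0.97
MMP-9,ChemScore,30.36,1.72
MMP-9,ASP,52.23,0.94
HSP90,CHEMPLP,58.22,2.54
HSP90,GoldScore,35.29,1.90
HSP90,ChemScore,21.71,2.62
HSP90,ASP,28.15,2.18
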