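target,consensus_z,rmsd
MMP-2,10.25,0.89
MMP-9,4.97,1.87
HSP90,9.24,0.56
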