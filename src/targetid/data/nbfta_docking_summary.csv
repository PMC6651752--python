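target,aggregated_z
MMP-2,5.69
MMP-9,5.02
HSP90,3.60
TRPV1,5.77
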