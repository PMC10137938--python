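protein,n_trp,inhibition_pct
WT,0,27.07
Mut1,6,36.56
Mut2,8,46.48
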