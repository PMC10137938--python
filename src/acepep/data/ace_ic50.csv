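rank,peptide,ic50_uM,sd_uM,censored
1,WWNW,26.44,3.81,False
2,WFSW,147.83,14.27,False
3,WRFF,140.93,3.90,False
4,WRQF,29.58,6.75,False
5,WFRV,31.75,0.83,False
6,RWWD,128.90,8.32,False
7,YYWK,19.98,8.19,False
8,WWDW,36.76,1.32,False
9,WWTY,28.50,0.99,False
10,RRYQ,114.7,6.15,False
15999,GGSG,5000,,True
160000,SGGG,5000,,True
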