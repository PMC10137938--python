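rank,complex,e_vdw,e_ele,g_gb,g_np,dh,minus_tds,dg_bind
1,ACE-WWNW,-37.16,-32.50,33.11,-3.00,-39.54,12.19,-27.35
2,ACE-WFSW,-36.32,-43.52,41.12,-2.84,-41.56,19.86,-21.70
3,ACE-WRFF,-23.35,-38.23,41.48,-2.39,-22.50,13.12,-9.37
4,ACE-WRQF,-26.49,-58.36,55.04,-2.85,-32.66,12.36,-20.31
5,ACE-WRFV,-32.31,-52.88,49.07,-2.67,-38.78,13.68,-25.11
6,ACE-RWWD,-24.55,-50.01,50.40,-2.35,-26.60,20.79,-5.71
7,ACE-YYWK,-27.34,-49.40,49.47,-2.45,-29.72,11.45,-18.27
8,ACE-WWDW,-42.35,-7.87,14.14,-2.82,-38.90,17.98,-20.92
9,ACE-WWTY,-37.50,-42.12,39.43,-2.80,-42.98,16.53,-26.46
10,ACE-RRTQ,-28.42,-65.03,70.99,-2.45,-24.91,11.20,-13.71
159999,ACE-GGSG,-12.60,-19.67,16.57,-1.39,-17.08,13.79,-3.29
160000,ACE-SGGG,-14.51,16.93,-4.65,-1.26,-3.49,12.05,8.55
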