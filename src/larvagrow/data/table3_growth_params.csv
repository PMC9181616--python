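temperature_c,parameter,food,unit,value,se,p_printed
13,L_inf,,um,595.83,43.77,<0.001
13,a,,um/d,63.71,,
13,b,,1/d,0.107,0.026,<0.001
13,c,fed,1/d,0.012,0.001,<0.001
13,c,non_fed,1/d,0.010,0.001,<0.001
15,L_inf,,um,481.59,15.02,<0.001
15,a,,um/d,126.92,,
15,b,,1/d,0.263,0.051,<0.001
15,c,fed,1/d,0.013,0.001,<0.001
15,c,non_fed,1/d,0.005,0.001,<0.001
17,L_inf,,um,512.61,29.15,<0.001
17,a,,um/d,110.61,,
17,b,,1/d,0.216,0.060,<0.001
17,c,fed,1/d,0.006,0.001,<0.001
17,c,non_fed,1/d,0.006,0.001,<0.001
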