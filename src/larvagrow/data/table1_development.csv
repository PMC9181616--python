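temperature_c,time_dpf,stage,mean_um,sd_um,n,mouth_anus_open,gut_present
15,1,Embryo,159,8,73,no,no
15,3,Trochophore,169,14,91,no,no
15,6,1S,255,28,48,no,no
15,9,2S,356,15,8,no,no
15,12,3S,383,34,12,no,no
15,14,4S,476,33,23,yes,no
15,17,4S,465,52,22,yes,yes
15,20,5S,506,66,16,yes,yes
15,24,6S,499,86,16,yes,yes
15,43,7S,541,157,6,yes,yes
15,50,8S,746,258,22,yes,yes
13,8,2S,246,11,5,no,no
13,13,3S,415,30,10,no,no
13,16,4S,471,69,8,yes,no
13,21,5S,510,46,5,yes,yes
13,24,6S,461,,1,yes,yes
13,43,7S,674,76,4,yes,yes
13,50,7S,800,129,5,yes,yes
17,8,2S,276,19,11,no,no
17,11,3S,371,21,9,no,no
17,14,4S,454,30,19,yes,no
17,16,5S,445,40,8,yes,no
17,17,5S,459,45,10,yes,yes
17,21,6S,588,95,6,yes,yes
17,37,7S,551,155,18,yes,yes
17,43,8S,586,204,20,yes,yes
17,50,10S,544,186,21,yes,yes
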