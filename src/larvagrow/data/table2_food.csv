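temperature_c,time_dpf,food,mean_um,sd_um,n
13,21,non_fed,551,74,12
13,21,fed,505,51,4
13,24,non_fed,543,79,13
13,24,fed,461,,1
13,27,non_fed,594,65,8
13,27,fed,497,64,9
13,29,non_fed,626,132,7
13,29,fed,463,25,2
13,37,non_fed,651,120,14
13,37,fed,561,64,5
13,43,non_fed,626,102,11
13,43,fed,674,76,4
13,50,non_fed,659,96,12
13,50,fed,800,129,5
15,17,non_fed,465,84,12
15,17,fed,465,52,22
15,21,non_fed,468,80,7
15,21,fed,472,34,7
15,24,non_fed,465,71,12
15,24,fed,499,86,16
15,27,non_fed,511,95,19
15,27,fed,485,78,13
15,29,non_fed,514,113,15
15,29,fed,467,68,15
15,37,non_fed,556,77,13
15,37,fed,583,85,14
15,43,non_fed,613,154,9
15,43,fed,541,157,6
15,50,non_fed,487,110,23
15,50,fed,746,258,22
17,17,non_fed,476,57,11
17,17,fed,459,45,10
17,21,non_fed,500,70,11
17,21,fed,588,95,6
17,24,non_fed,420,70,10
17,24,fed,485,66,8
17,27,non_fed,466,133,10
17,27,fed,505,107,12
17,29,non_fed,463,72,11
17,29,fed,473,57,8
17,37,non_fed,514,125,13
17,37,fed,551,155,18
17,43,non_fed,687,265,16
17,43,fed,586,204,20
17,50,non_fed,506,212,17
17,50,fed,544,186,21
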