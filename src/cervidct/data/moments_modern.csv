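species,n,biomarker,mean,sd
reindeer,22,tb_n,3.51,0.37
reindeer,22,tb_sp,0.18,0.04
reindeer,22,tb_th,0.19,0.03
reindeer,22,tb_pf,-14.28,3.92
reindeer,22,smi,-3.01,1.06
reindeer,22,bv_tv,65.73,6.48
red_deer,17,tb_n,2.83,0.45
red_deer,17,tb_sp,0.24,0.04
red_deer,17,tb_th,0.23,0.08
red_deer,17,tb_pf,-10.53,3.99
red_deer,17,smi,-2.77,1.57
red_deer,17,bv_tv,63.04,10.8
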