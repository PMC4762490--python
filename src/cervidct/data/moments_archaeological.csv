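species,n,biomarker,mean,sd
reindeer,27,tb_n,2.67,0.64
reindeer,27,tb_sp,0.22,0.07
reindeer,27,tb_th,0.20,0.10
reindeer,27,tb_pf,-6.02,9.21
reindeer,27,smi,-2.14,3.65
reindeer,27,bv_tv,53.62,25.17
red_deer,23,tb_n,2.67,0.59
red_deer,23,tb_sp,0.26,0.05
red_deer,23,tb_th,0.26,0.09
red_deer,23,tb_pf,-11.25,3.62
red_deer,23,smi,-3.39,1.88
red_deer,23,bv_tv,65.59,11.76
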