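source,target,s_mgy_per_mbq_s,ref_mass_g
red_marrow,red_marrow,1.9e-05,1170
kidney_L,red_marrow,8.7e-08,155
kidney_R,red_marrow,8.7e-08,155
rob,red_marrow,2.0e-07,70000
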