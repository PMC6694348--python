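patient,mc1_mgy,mc2_mgy,gmc3_mgy,smird_mgy
P8,1223,225,718,46
P9,684,202,408,40
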