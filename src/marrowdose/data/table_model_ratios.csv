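patient,mc1_smird,mc2_smird,mc1_mc2
P1,17,3,6
P2,3,3,1
P3,5,3,2
P4,50,4,11
P5,18,4,4
P6,1,1,1
P7,37,4,9
P8,27,5,5
P9,17,5,3
P10,12,5,2
P11,11,6,2
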