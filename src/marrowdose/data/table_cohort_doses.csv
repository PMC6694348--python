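patient,activity_gbq,smird_mgy,mc1_mgy,mc2_mgy,bone_lesion_load_ml,ti_tumor_uptake_gbq_s_ml,ti_rob_retention_gbq_s_ml
P1,3.7,30,493,81,402,141,3
P2,3.7,41,109,109,33,87,4
P3,3.7,52,274,137,448,59,5
P4,3.7,63,3192,281,1123,609,4
P5,6.0,120,2139,515,1124,523,17
P6,6.0,36,22,22,50,9,16
P7,6.0,150,5595,635,727,1130,26
P8,6.0,46,1223,225,1298,159,10
P9,6.0,40,684,202,836,128,9
P10,6.1,66,782,347,138,384,17
P11,6.1,36,403,206,467,64,9
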