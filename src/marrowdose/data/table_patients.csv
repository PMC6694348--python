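patient,age,activity_gbq,cycle,leukocytes_g_l,lymphocytes_g_l,hemoglobin_g_dl,thrombocytes_g_l,erythrocytes_t_l
P1,66,3.7,1,7.2,0.57,14.1,195,4.79
P2,68,3.7,1,4.96,0.96,12.3,307,4.31
P3,47,3.7,1,5.6,1.71,12.8,323,4.36
P4,61,3.7,1,5.2,0.49,9.6,291,4.08
P5,73,6.0,1,4.54,0.56,10.9,235,3.86
P6,63,6.0,1,5.41,1.14,13.3,227,4.11
P7,82,6.0,1,4.85,0.95,10.5,450,3.96
P8,83,6.0,5,5.31,0.48,8.4,305,3.25
P9,79,6.0,1,2.73,0.94,10.5,223,3.55
P10,67,6.1,1,7.84,0.28,8.3,89,3.2
P11,88,6.1,1,,2.06,12.1,281,3.64
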