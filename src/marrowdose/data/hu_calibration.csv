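hu,density_g_cm3,tissue_class
-1000,0.0012,air
-950,0.093,lung
-150,0.850,soft_tissue
0,1.000,soft_tissue
200,1.100,bone
1000,1.900,bone
2000,2.400,bone
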