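medium,z_over_a,density_g_cm3
water,0.5551,1.0
air,0.4992,0.0012
lung,0.55,0.26
soft_tissue,0.55,1.03
bone_cortical,0.5148,1.92
marrow_red,0.5519,1.03
marrow_yellow,0.5558,0.98
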