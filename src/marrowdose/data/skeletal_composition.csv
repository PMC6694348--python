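region_id,region,f_bm,f_iabm,f_hb
1,skull,0.10,0.35,0.55
2,mandible,0.05,0.35,0.60
3,cervical_spine,0.28,0.32,0.40
4,thoracic_spine,0.30,0.35,0.35
5,lumbar_spine,0.32,0.38,0.30
6,sacrum,0.30,0.40,0.30
7,sternum,0.25,0.40,0.35
8,ribs,0.20,0.35,0.45
9,clavicles,0.10,0.40,0.50
10,scapulae,0.15,0.40,0.45
11,os_coxae,0.30,0.35,0.35
12,humeri_proximal,0.12,0.48,0.40
13,femora_proximal,0.15,0.45,0.40
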