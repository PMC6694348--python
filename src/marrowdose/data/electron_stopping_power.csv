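energy_keV,water,air,lung,soft_tissue,bone_cortical,marrow_red,marrow_yellow
1,126.4,111.232,124.504,124.504,115.656,126.4,130.192
2,77.9,68.552,76.7315,76.7315,71.2785,77.9,80.237
3,59.2,52.096,58.312,58.312,54.168,59.2,60.976
5,41.9,36.872,41.2715,41.2715,38.3385,41.9,43.157
7,32.5,28.6,32.0125,32.0125,29.7375,32.5,33.475
10,22.56,19.8528,22.2216,22.2216,20.6424,22.56,23.2368
15,16.47,14.4936,16.2229,16.2229,15.0701,16.47,16.9641
20,13.17,11.5896,12.9725,12.9725,12.0506,13.17,13.5651
30,9.65,8.492,9.50525,9.50525,8.82975,9.65,9.9395
40,7.78,6.8464,7.6633,7.6633,7.1187,7.78,8.0134
50,6.6,5.808,6.501,6.501,6.039,6.6,6.798
70,5.26,4.6288,5.1811,5.1811,4.8129,5.26,5.4178
100,4.115,3.6212,4.05328,4.05328,3.76523,4.115,4.23845
150,3.24,2.8512,3.1914,3.1914,2.9646,3.24,3.3372
200,2.79,2.4552,2.74815,2.74815,2.55285,2.79,2.8737
300,2.36,2.0768,2.3246,2.3246,2.1594,2.36,2.4308
400,2.15,1.892,2.11775,2.11775,1.96725,2.15,2.2145
500,2.03,1.7864,1.99955,1.99955,1.85745,2.03,2.0909
600,1.96,1.7248,1.9306,1.9306,1.7934,1.96,2.0188
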