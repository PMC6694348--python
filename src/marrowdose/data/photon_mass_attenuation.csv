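energy_keV,water,air,lung,soft_tissue,bone_cortical,marrow_red,marrow_yellow
1,12349.7,11870.3,12555.1,12555.1,29120.2,12555.1,7761.43
1.5,3175.21,3051.94,3228.03,3228.03,8628.35,3228.03,1995.59
2,1211.37,1164.33,1231.52,1231.52,3640.2,1231.52,761.386
3,311.6,299.491,316.778,316.778,1078.72,316.779,195.912
4,119,114.367,120.974,120.974,455.203,120.975,74.869
5,56.465,54.2597,57.3987,57.3987,233.162,57.3995,35.5676
6,30.7554,29.5481,31.2614,31.2614,135.016,31.2621,19.4097
8,11.8649,11.391,12.0567,12.0567,57.075,12.0575,7.5371
10,5.73041,5.49472,5.82021,5.82021,29.3186,5.82094,3.68118
15,1.62848,1.55225,1.65014,1.65014,8.82314,1.65086,1.10183
20,0.747591,0.705787,0.754693,0.754693,3.83159,0.7554,0.546852
30,0.338829,0.313316,0.339308,0.339308,1.26376,0.339992,0.287405
40,0.246528,0.224986,0.245633,0.245633,0.634425,0.246295,0.227059
50,0.212835,0.192957,0.211528,0.211528,0.407043,0.212171,0.203737
60,0.19604,0.177142,0.194591,0.194591,0.303972,0.195215,0.191202
80,0.178131,0.160514,0.176628,0.176628,0.217248,0.17722,0.176415
100,0.167189,0.150505,0.165716,0.165716,0.181886,0.16628,0.166481
150,0.14893,0.133971,0.147578,0.147578,0.146158,0.148085,0.148881
200,0.136128,0.122434,0.134883,0.134883,0.129661,0.135348,0.136209
250,0.126225,0.113521,0.125068,0.125068,0.118819,0.1255,0.126342
300,0.11822,0.106318,0.117135,0.117135,0.110658,0.117539,0.118346
400,0.105889,0.095227,0.104917,0.104917,0.0986344,0.105279,0.106014
500,0.0966788,0.0869437,0.0957908,0.0957908,0.0898825,0.0961217,0.0967965
600,0.0894297,0.0804243,0.0886083,0.0886083,0.0830663,0.0889143,0.0895402
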