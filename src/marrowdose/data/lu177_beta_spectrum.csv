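e_lo_keV,e_hi_keV,probability
0,5,0.025565683
5,10,0.025226261
10,15,0.024877062
15,20,0.024518691
20,25,0.024151819
25,30,0.023777156
30,35,0.023395417
35,40,0.023007304
40,45,0.02261351
45,50,0.022214716
50,55,0.021811603
55,60,0.021404854
60,65,0.020995163
65,70,0.020583241
70,75,0.020169812
75,80,0.019755623
80,85,0.019341443
85,90,0.018928062
90,95,0.018516297
95,100,0.018106985
100,105,0.01770099
105,110,0.0172992
110,115,0.016902528
115,120,0.016511909
120,125,0.016128304
125,130,0.015752699
130,135,0.0153861
135,140,0.01502954
140,145,0.014684074
145,150,0.01435078
150,155,0.014030759
155,160,0.013725135
160,165,0.013435054
165,170,0.013161685
170,175,0.01290622
175,180,0.012669749
180,185,0.012439018
185,190,0.012204545
190,195,0.011966504
195,200,0.011725078
200,205,0.011480452
205,210,0.011232819
210,215,0.010982374
215,220,0.01072932
220,225,0.010473863
225,230,0.010216215
230,235,0.0099565925
235,240,0.0096952177
240,245,0.009432317
245,250,0.0091681221
250,255,0.0089028694
255,260,0.0086368002
260,265,0.0083701609
265,270,0.0081032024
270,275,0.0078361805
275,280,0.007569356
280,285,0.0073029942
285,290,0.0070373654
290,295,0.0067727445
295,300,0.0065094113
300,305,0.0062476503
305,310,0.0059877506
310,315,0.0057300062
315,320,0.0054747157
320,325,0.0052221825
325,330,0.0049727145
330,335,0.0047266246
335,340,0.0044842301
340,345,0.0042458531
345,350,0.0040118204
350,355,0.0037824634
355,360,0.0035581183
360,365,0.0033391258
365,370,0.0031258313
370,375,0.0029185848
375,380,0.0027177411
380,385,0.0025236595
385,390,0.0023364543
390,395,0.0021545372
395,400,0.0019777931
400,405,0.0018065105
405,410,0.0016409816
410,415,0.0014815021
415,420,0.0013283715
420,425,0.0011818928
425,430,0.0010423728
430,435,0.00091012178
435,440,0.00078545376
440,445,0.00066868635
445,450,0.00056014078
450,455,0.00046014193
455,460,0.0003690183
460,465,0.00028710202
465,470,0.00021472885
470,475,0.00015223816
475,480,9.9972968e-05
480,485,5.8279896e-05
485,490,2.7509196e-05
490,495,8.0147416e-06
495,500,1.5402607e-07
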