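compound,exp_ic50,pred_ic50,fit,error,exp_scale,pred_scale
1,0.0002,0.000276612,11.8863,1.38306,+++,+++
2,0.0005,0.000633086,11.5267,1.26617,+++,+++
3,0.007,0.013691,10.1918,1.95586,+++,+++
4,0.0071,0.0157362,10.1313,2.21637,+++,++
5,0.01,0.0144282,10.169,1.44282,+++,+++
6,0.019,0.0579635,9.56505,3.05071,+++,+++
7,0.025,0.0126119,10.2274,-1.98225,+++,+++
8,0.028,0.0287705,9.86925,1.02752,+++,+++
9,0.034,0.012146,10.2438,-2.79928,+++,+++
10,0.0495,0.0896702,9.37555,1.81152,+++,+++
11,0.0585,0.0555811,9.58327,-1.05252,+++,+++
12,0.2,0.194532,9.03921,-1.02811,++,++
13,0.8112,0.990206,8.33247,1.22067,++,++
14,2.59,2.31136,7.96433,-1.12055,++,++
15,2.9,3.51633,7.78211,1.21253,++,+
16,3.32,2.3407,7.95885,-1.41838,+,++
17,4.4,2.47184,7.93518,-1.78005,+,++
18,4.8,6.61342,7.50777,1.3778,+,+
19,7.02,4.71511,7.65471,-1.48883,+,+
20,7.5,3.51889,7.78179,-2.13135,+,+
21,9.8,4.26887,7.69789,-2.29569,+,+
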