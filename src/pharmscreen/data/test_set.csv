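compound,exp_ic50,pred_ic50,fit,error,exp_scale,pred_scale
1,0.00036,0.000896414,11.3757,2.49004,+++,+++
2,0.00049,0.000209471,12.0071,-2.33923,+++,+++
3,0.021,0.00797192,10.4266,-2.63425,+++,+++
4,0.031,0.019866,10.0301,-1.56046,+++,+++
5,0.04,0.0582672,9.56278,1.45668,+++,+++
6,0.072,0.0672314,9.50063,-1.07093,+++,+++
7,0.084,0.147936,9.15812,1.76117,+++,++
8,0.116,0.169831,9.09818,1.46406,++,++
9,0.12,0.584101,8.56171,4.86751,++,++
10,0.18,0.171855,9.09304,-1.04739,++,++
11,0.25,0.787807,8.43178,3.15123,++,++
12,0.4,0.647081,8.51724,1.6177,++,++
13,0.43,0.148644,9.15605,-2.89282,++,++
14,0.563,1.40413,8.18079,2.49401,++,++
15,0.62,0.291697,8.86327,-2.12549,++,++
16,0.66,0.543583,8.59293,-1.21417,++,++
17,0.67,0.902735,8.37264,1.34734,++,++
18,0.83,0.390716,8.73634,-2.12431,++,++
19,0.84,0.705346,8.4798,-1.1909,++,++
20,0.872,0.302548,8.84741,-2.88219,++,++
21,0.89,0.304132,8.84514,-2.92636,++,++
22,0.95,1.05843,8.30354,1.11414,++,++
23,0.99,0.278074,8.88404,-3.5602,++,++
24,1.02,4.48861,7.67609,4.4006,++,+
25,1.04,1.41841,8.1764,1.36386,++,++
26,1.13,0.560729,8.57945,-2.01523,++,++
27,1.44,1.44555,8.16817,1.00385,++,++
28,1.54,2.29464,7.96749,1.49003,++,++
29,1.69,0.466732,8.65913,-3.62092,++,++
30,1.76,1.66113,8.1078,-1.05952,++,++
31,1.83,0.370472,8.75944,-4.93964,++,++
32,1.89,2.79708,7.8815,1.47994,++,++
33,2.37,0.58676,8.55974,-4.03913,++,++
34,2.76,2.11978,8.00191,-1.30202,++,++
35,2.96,9.16837,7.36591,3.09742,++,+
36,8.53,2.35434,7.95633,-3.6231,+,++
37,8.95,2.32546,7.96169,-3.8487,+,++
38,9.25,2.76764,7.88609,-3.3422,+,++
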