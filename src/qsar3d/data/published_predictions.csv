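compound_id,pki_exp,comfa_pred,comfarf_pred,comsia_pred
1,6.376751,6.774,7.23,6.972
2,7.366532,6.953,7.36,7.026
3,6.754487,6.893,7.041,6.998
4,6.931814,6.846,6.991,6.729
5,6.91364,6.835,6.78,7.015
6,6.866461,6.773,6.83,7.066
7,6.625252,6.495,6.991,7.02
8,6.815309,6.955,7.105,6.992
9,7.337242,7.369,7.505,7.008
10,8.017729,8.016,7.107,7.068
11,6.578396,7.406,6.81,6.672
12,8.05061,8.088,7.9,7.924
13,6.419075,6.376,7.188,7.049
14,7.420216,7.452,7.53,7.315
15,7.443697,7.342,7.46,7.446
16,7.508638,7.388,7.58,7.474
17,8.040959,8.101,8.11,7.902
18,6.742321,6.836,7.477,7.256
19,6.309804,6.346,6.17,6.132
20,6.106793,6.152,6.25,6.138
21,7.677781,8.262,8.148,8.245
22,8.251812,8.095,8.17,8.289
23,7.468521,8.564,7.95,8.028
24,7.995679,7.565,8.054,8.111
25,8.346787,8.248,8.06,8.095
26,8.39794,8.218,8.04,8.03
27,6.442493,6.795,8,8.062
28,8.022276,8.174,8.3,8.259
29,6.619789,6.683,6.484,6.479
30,6.493495,6.534,6.299,6.519
31,6.488117,6.617,6.24,6.262
32,6.251812,6.292,6.23,6.306
33,6.237321,6.333,6.24,6.32
34,6.505845,6.759,6.29,6.269
35,6.166853,5.786,6.35,6.292
36,8.031517,8.070,7.43,7.37
37,8.036212,7.953,7.42,7.419
38,6.732828,7.915,6.86,7.142
39,6.61261,7.451,7.06,7.193
40,6.74958,7.464,7.23,7.202
41,7.19382,7.951,7.35,7.169
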