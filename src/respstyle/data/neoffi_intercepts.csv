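item,scale,c1,c2,c3,c4,c5
1,N,-0.971,1.583,0.385,1.153,-2.150
2,N,-0.833,2.262,1.258,0.971,-3.659
3,N,-1.281,2.457,0.978,1.224,-3.377
4,N,-0.551,2.607,0.721,0.675,-3.452
5,N,-0.571,3.092,1.318,0.762,-4.600
6,N,0.685,2.702,0.507,0.524,-4.417
7,N,-2.016,2.366,1.127,1.496,-2.972
8,N,-0.251,3.304,1.193,0.208,-4.454
9,N,-0.501,3.390,1.504,0.936,-5.329
10,N,-1.103,2.944,1.023,1.044,-3.908
11,N,0.686,3.540,1.151,0.611,-5.988
12,N,0.044,3.109,0.753,0.715,-4.621
13,A,-3.843,-1.539,-0.389,3.514,2.258
14,A,-3.570,-0.478,0.490,2.829,0.730
15,A,-4.542,0.997,1.349,2.691,-0.495
16,A,-4.194,0.074,0.799,3.059,0.262
17,A,-3.719,0.291,0.772,2.556,0.101
18,A,-3.543,1.344,0.754,2.465,-1.019
19,A,-4.470,-0.202,1.264,3.847,-0.439
20,A,-1.189,0.118,2.103,-1.032,0.000
21,A,-3.089,1.051,1.045,2.270,-1.277
22,A,-3.822,-1.276,3.632,1.466,0.000
23,A,-4.029,0.384,1.266,2.982,-0.604
24,A,-5.305,0.181,0.832,3.319,0.973
25,C,-3.710,0.265,0.776,2.418,0.252
26,C,-3.815,0.122,0.505,2.964,0.223
27,C,-3.561,0.686,0.800,2.471,-0.396
28,C,-5.826,-1.564,-0.046,4.588,2.848
29,C,-4.776,0.274,1.368,3.085,0.049
30,C,-4.359,0.869,0.916,2.996,-0.421
31,C,-6.060,-0.827,0.893,4.240,1.755
32,C,-5.423,-1.183,0.471,4.133,2.002
33,C,-4.715,1.497,1.095,2.918,-0.795
34,C,-6.140,0.072,1.711,3.717,0.639
35,C,-4.710,0.606,0.894,3.173,0.038
36,C,-5.167,0.626,1.692,3.104,-0.256
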