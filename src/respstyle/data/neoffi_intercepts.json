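{
 "description": "Published NEO-FFI category intercept estimates (N/A/C subscales, four-dimensional constrained model, n=1188 older adults)",
 "n_categories": 5,
 "substantive_slopes": [
  -1,
  -0.5,
  0,
  0.5,
  1
 ],
 "ers_slopes": [
  0.75,
  -0.5,
  -0.5,
  -0.5,
  0.75
 ],
 "items": [
  {
   "item": 1,
   "scale": "N",
   "intercepts": [
    -0.971,
    1.583,
    0.385,
    1.153,
    -2.15
   ]
  },
  {
   "item": 2,
   "scale": "N",
   "intercepts": [
    -0.833,
    2.262,
    1.258,
    0.971,
    -3.659
   ]
  },
  {
   "item": 3,
   "scale": "N",
   "intercepts": [
    -1.281,
    2.457,
    0.978,
    1.224,
    -3.377
   ]
  },
  {
   "item": 4,
   "scale": "N",
   "intercepts": [
    -0.551,
    2.607,
    0.721,
    0.675,
    -3.452
   ]
  },
  {
   "item": 5,
   "scale": "N",
   "intercepts": [
    -0.571,
    3.092,
    1.318,
    0.762,
    -4.6
   ]
  },
  {
   "item": 6,
   "scale": "N",
   "intercepts": [
    0.685,
    2.702,
    0.507,
    0.524,
    -4.417
   ]
  },
  {
   "item": 7,
   "scale": "N",
   "intercepts": [
    -2.016,
    2.366,
    1.127,
    1.496,
    -2.972
   ]
  },
  {
   "item": 8,
   "scale": "N",
   "intercepts": [
    -0.251,
    3.304,
    1.193,
    0.208,
    -4.454
   ]
  },
  {
   "item": 9,
   "scale": "N",
   "intercepts": [
    -0.501,
    3.39,
    1.504,
    0.936,
    -5.329
   ]
  },
  {
   "item": 10,
   "scale": "N",
   "intercepts": [
    -1.103,
    2.944,
    1.023,
    1.044,
    -3.908
   ]
  },
  {
   "item": 11,
   "scale": "N",
   "intercepts": [
    0.686,
    3.54,
    1.151,
    0.611,
    -5.988
   ]
  },
  {
   "item": 12,
   "scale": "N",
   "intercepts": [
    0.044,
    3.109,
    0.753,
    0.715,
    -4.621
   ]
  },
  {
   "item": 13,
   "scale": "A",
   "intercepts": [
    -3.843,
    -1.539,
    -0.389,
    3.514,
    2.258
   ]
  },
  {
   "item": 14,
   "scale": "A",
   "intercepts": [
    -3.57,
    -0.478,
    0.49,
    2.829,
    0.73
   ]
  },
  {
   "item": 15,
   "scale": "A",
   "intercepts": [
    -4.542,
    0.997,
    1.349,
    2.691,
    -0.495
   ]
  },
  {
   "item": 16,
   "scale": "A",
   "intercepts": [
    -4.194,
    0.074,
    0.799,
    3.059,
    0.262
   ]
  },
  {
   "item": 17,
   "scale": "A",
   "intercepts": [
    -3.719,
    0.291,
    0.772,
    2.556,
    0.101
   ]
  },
  {
   "item": 18,
   "scale": "A",
   "intercepts": [
    -3.543,
    1.344,
    0.754,
    2.465,
    -1.019
   ]
  },
  {
   "item": 19,
   "scale": "A",
   "intercepts": [
    -4.47,
    -0.202,
    1.264,
    3.847,
    -0.439
   ]
  },
  {
   "item": 20,
   "scale": "A",
   "intercepts": [
    -1.189,
    0.118,
    2.103,
    -1.032,
    0.0
   ]
  },
  {
   "item": 21,
   "scale": "A",
   "intercepts": [
    -3.089,
    1.051,
    1.045,
    2.27,
    -1.277
   ]
  },
  {
   "item": 22,
   "scale": "A",
   "intercepts": [
    -3.822,
    -1.276,
    3.632,
    1.466,
    0.0
   ]
  },
  {
   "item": 23,
   "scale": "A",
   "intercepts": [
    -4.029,
    0.384,
    1.266,
    2.982,
    -0.604
   ]
  },
  {
   "item": 24,
   "scale": "A",
   "intercepts": [
    -5.305,
    0.181,
    0.832,
    3.319,
    0.973
   ]
  },
  {
   "item": 25,
   "scale": "C",
   "intercepts": [
    -3.71,
    0.265,
    0.776,
    2.418,
    0.252
   ]
  },
  {
   "item": 26,
   "scale": "C",
   "intercepts": [
    -3.815,
    0.122,
    0.505,
    2.964,
    0.223
   ]
  },
  {
   "item": 27,
   "scale": "C",
   "intercepts": [
    -3.561,
    0.686,
    0.8,
    2.471,
    -0.396
   ]
  },
  {
   "item": 28,
   "scale": "C",
   "intercepts": [
    -5.826,
    -1.564,
    -0.046,
    4.588,
    2.848
   ]
  },
  {
   "item": 29,
   "scale": "C",
   "intercepts": [
    -4.776,
    0.274,
    1.368,
    3.085,
    0.049
   ]
  },
  {
   "item": 30,
   "scale": "C",
   "intercepts": [
    -4.359,
    0.869,
    0.916,
    2.996,
    -0.421
   ]
  },
  {
   "item": 31,
   "scale": "C",
   "intercepts": [
    -6.06,
    -0.827,
    0.893,
    4.24,
    1.755
   ]
  },
  {
   "item": 32,
   "scale": "C",
   "intercepts": [
    -5.423,
    -1.183,
    0.471,
    4.133,
    2.002
   ]
  },
  {
   "item": 33,
   "scale": "C",
   "intercepts": [
    -4.715,
    1.497,
    1.095,
    2.918,
    -0.795
   ]
  },
  {
   "item": 34,
   "scale": "C",
   "intercepts": [
    -6.14,
    0.072,
    1.711,
    3.717,
    0.639
   ]
  },
  {
   "item": 35,
   "scale": "C",
   "intercepts": [
    -4.71,
    0.606,
    0.894,
    3.173,
    0.038
   ]
  },
  {
   "item": 36,
   "scale": "C",
   "intercepts": [
    -5.167,
    0.626,
    1.692,
    3.104,
    -0.256
   ]
  }
 ]
}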