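energy_keV,relative_fluence
2.0,0.00000000e+00
4.0,4.14977082e-157
6.0,5.99530756e-51
8.0,6.65224210e-23
10.0,1.48158961e-12
12.0,6.41585837e-08
14.0,1.44045894e-05
16.0,2.88737443e-04
18.0,1.70455045e-03
20.0,5.17329517e-03
22.0,1.01903884e-02
24.0,1.60799513e-02
26.0,2.19505241e-02
28.0,2.71726230e-02
30.0,3.14309310e-02
32.0,3.38683320e-02
34.0,3.55163225e-02
36.0,3.64895445e-02
38.0,3.69067734e-02
40.0,3.68781137e-02
42.0,3.61069905e-02
44.0,3.51736597e-02
46.0,3.41224011e-02
48.0,3.29883225e-02
50.0,3.17990689e-02
52.0,3.04103683e-02
54.0,2.90449854e-02
56.0,2.77081186e-02
58.0,5.00791611e-02
60.0,6.57593169e-02
62.0,2.38092272e-02
64.0,2.25409744e-02
66.0,2.13255458e-02
68.0,3.23710404e-02
70.0,2.22968307e-02
72.0,1.79689183e-02
74.0,1.69381891e-02
76.0,1.59476733e-02
78.0,1.49952536e-02
80.0,1.40789380e-02
82.0,1.31742143e-02
84.0,1.23063517e-02
86.0,1.14731270e-02
88.0,1.06724925e-02
90.0,9.90255909e-03
92.0,9.16158109e-03
94.0,8.44794302e-03
96.0,7.76014766e-03
98.0,7.09680538e-03
100.0,6.45662471e-03
102.0,5.83271576e-03
104.0,5.23103380e-03
106.0,4.65039061e-03
108.0,4.08968195e-03
110.0,3.54788019e-03
112.0,3.02402775e-03
114.0,2.51723121e-03
116.0,2.02665599e-03
118.0,1.55152156e-03
120.0,1.09109711e-03
122.0,6.44697644e-04
124.0,2.11680398e-04
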