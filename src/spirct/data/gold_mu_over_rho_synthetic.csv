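energy_keV,mu_over_rho_cm2_per_g
1.0000,461397
2.0000,64102.3
3.0000,20217.6
4.0000,8919.85
5.0000,4730
6.0000,2817.65
7.0000,1818.76
8.0000,1245.05
9.0000,891.429
10.0000,661.246
11.0000,504.755
12.0000,394.522
13.0000,314.549
14.0000,255.067
15.0000,209.872
16.0000,174.893
17.0000,147.38
18.0000,125.43
19.0000,107.694
20.0000,93.2015
21.0000,81.2377
22.0000,71.2702
23.0000,62.8963
24.0000,55.8073
25.0000,49.7639
26.0000,44.5787
27.0000,40.1033
28.0000,36.2193
29.0000,32.8312
30.0000,29.8618
31.0000,27.2476
32.0000,24.9367
33.0000,22.8859
34.0000,21.0593
35.0000,19.4267
36.0000,17.9629
37.0000,16.6463
38.0000,15.4587
39.0000,14.3846
40.0000,13.4105
41.0000,12.525
42.0000,11.7181
43.0000,10.9812
44.0000,10.3067
45.0000,9.68821
46.0000,9.11988
47.0000,8.59669
48.0000,8.11418
49.0000,7.66845
50.0000,7.256
51.0000,6.87375
52.0000,6.51896
53.0000,6.18918
54.0000,5.8822
55.0000,5.59607
56.0000,5.32903
57.0000,5.07949
58.0000,4.84602
59.0000,4.62733
60.0000,4.42226
61.0000,4.22974
62.0000,4.04882
63.0000,3.87863
64.0000,3.71836
65.0000,3.56731
66.0000,3.4248
67.0000,3.29023
68.0000,3.16305
69.0000,3.04275
70.0000,2.92886
71.0000,2.82096
72.0000,2.71865
73.0000,2.62157
74.0000,2.52938
75.0000,2.44178
76.0000,2.35847
77.0000,2.2792
78.0000,2.20372
79.0000,2.13179
80.0000,2.06322
80.7249,2.0155
80.7249,8.904
81.0000,8.82707
82.0000,8.55516
83.0000,8.29488
84.0000,8.04561
85.0000,7.80675
86.0000,7.57775
87.0000,7.3581
88.0000,7.14731
89.0000,6.94493
90.0000,6.75054
91.0000,6.56374
92.0000,6.38415
93.0000,6.21141
94.0000,6.04521
95.0000,5.88522
96.0000,5.73115
97.0000,5.58272
98.0000,5.43967
99.0000,5.30175
100.0000,5.16873
101.0000,5.04039
102.0000,4.91652
103.0000,4.79693
104.0000,4.68141
105.0000,4.56981
106.0000,4.46195
107.0000,4.35766
108.0000,4.25681
109.0000,4.15924
110.0000,4.06483
111.0000,3.97343
112.0000,3.88494
113.0000,3.79922
114.0000,3.71618
115.0000,3.6357
116.0000,3.55769
117.0000,3.48204
118.0000,3.40867
119.0000,3.33749
120.0000,3.26842
121.0000,3.20137
122.0000,3.13628
123.0000,3.07306
124.0000,3.01166
125.0000,2.952
126.0000,2.89402
127.0000,2.83766
128.0000,2.78286
129.0000,2.72957
130.0000,2.67774
131.0000,2.62731
132.0000,2.57824
133.0000,2.53048
134.0000,2.48398
135.0000,2.43871
136.0000,2.39462
137.0000,2.35167
138.0000,2.30982
139.0000,2.26904
140.0000,2.2293
141.0000,2.19055
142.0000,2.15277
143.0000,2.11593
144.0000,2.08
145.0000,2.04495
146.0000,2.01075
147.0000,1.97737
148.0000,1.94479
149.0000,1.91299
150.0000,1.88194
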