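fragment_id,mean_mass,sd_mass,mean_migration,sd_migration,organs
1,14.25,0.45,20.68,0.08,lung;liver;kidney;muscle
2,15.53,0.30,20.95,0.05,muscle
3,17.61,0.34,21.34,0.06,muscle
4,19.65,0.62,21.81,0.13,kidney
5,25.58,0.73,21.94,0.15,liver
6,22.62,0.83,22.36,0.16,liver;kidney
7,23.84,0.38,22.56,0.07,muscle
8,24.54,0.37,22.66,0.06,lung;liver
9,25.63,0.69,22.93,0.15,kidney;muscle
10,26.83,0.35,23.12,0.08,lung;liver;muscle
11,29.43,0.50,23.57,0.14,lung;kidney
12,31.68,0.64,23.91,0.10,kidney;muscle
13,32.92,0.75,24.08,0.12,lung;liver;kidney
14,35.47,0.91,24.40,0.10,lung;liver;muscle
15,39.65,0.94,25.02,0.18,lung;liver;kidney;muscle
16,43.68,0.82,25.59,0.11,lung;liver;kidney;muscle
17,45.15,1.21,25.86,0.17,liver
18,47.34,0.91,26.19,0.12,kidney
19,50.20,1.11,26.46,0.13,lung;liver
20,51.97,0.47,26.69,0.09,kidney;muscle
21,53.06,0.65,26.86,0.08,liver
22,55.43,0.43,27.15,0.04,liver
23,57.44,1.10,27.32,0.16,lung;kidney;muscle
24,58.43,1.11,27.54,0.18,liver;kidney;muscle
25,62.89,0.70,28.08,0.08,muscle
26,71.58,1.57,28.80,0.27,lung;liver;kidney
27,74.83,1.49,28.99,0.16,lung;muscle
28,78.23,1.25,29.29,0.07,muscle
29,82.13,1.08,29.68,0.09,liver
30,84.57,0.77,29.88,0.07,kidney
31,85.91,0.98,29.90,0.09,lung;muscle
32,91.34,1.04,30.30,0.09,lung
33,93.95,1.91,30.59,0.16,lung;liver;kidney;muscle
34,104.86,1.01,31.59,0.08,liver
35,111.46,5.41,32.09,0.52,muscle
36,121.23,1.82,32.98,0.17,muscle
37,123.73,2.40,33.23,0.20,kidney;muscle
38,131.39,1.01,33.90,0.09,liver
39,135.25,2.04,34.20,0.17,lung;liver
40,141.40,1.35,34.71,0.15,lung;muscle
41,144.59,2.03,35.04,0.18,liver;muscle
42,154.94,1.46,35.78,0.11,lung;kidney
43,179.02,1.05,37.28,0.07,lung;liver;kidney
44,217.22,0.98,39.60,0.07,lung
45,225.04,3.44,40.08,0.21,lung
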