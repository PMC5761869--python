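patient,right_total_cm3,right_fg_cm3,right_density_pct,left_total_cm3,left_fg_cm3,left_density_pct
1,1009.57,20.42,2.02,977.06,24.07,2.46
2,885.04,176.15,19.90,894.37,197.47,22.07
3,736.21,176.81,24.02,708.45,169.35,23.90
4,817.87,48.24,5.90,783.33,47.11,6.01
5,762.06,71.86,9.43,657.97,91.38,13.89
6,768.52,41.76,5.43,867.20,54.80,6.32
7,858.45,64.54,7.52,780.86,64.25,8.23
8,682.62,33.83,4.96,699.73,35.85,5.12
9,860.79,42.84,4.98,857.37,63.39,7.39
10,830.06,44.06,5.31,839.73,50.92,6.06
11,246.68,38.02,15.41,183.75,34.51,18.78
12,707.59,64.60,9.13,863.97,35.03,4.05
13,905.65,43.43,4.79,810.98,57.30,7.07
14,980.14,47.29,4.82,950.29,73.73,7.76
15,624.06,18.97,3.04,330.07,20.13,6.10
16,158.83,30.54,19.23,167.51,33.65,20.09
17,492.67,24.10,4.89,604.73,29.30,4.85
18,510.75,16.09,3.15,510.50,21.29,4.17
19,757.46,42.51,5.61,742.87,39.56,5.32
20,1145.62,21.96,1.92,1346.01,28.87,2.14
21,525.74,31.35,5.96,465.34,31.07,6.68
22,687.88,48.34,7.03,731.17,47.88,6.55
23,839.80,227.23,27.06,729.95,198.37,27.18
24,397.11,22.35,5.63,449.21,28.65,6.38
25,1153.69,27.61,2.39,958.73,41.03,4.28
26,1177.88,250.62,21.28,1062.86,283.95,26.72
27,1086.62,34.71,3.19,1042.15,31.91,3.06
28,975.74,33.66,3.45,940.60,16.24,1.73
29,979.24,23.30,2.38,1037.98,34.47,3.32
30,672.68,39.94,5.94,564.10,45.94,8.14
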