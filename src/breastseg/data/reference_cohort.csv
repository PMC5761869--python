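patient,total_cm3,fg_cm3,density_pct,tumor_cm3
1,1986.64,44.49,2.24,4.47
2,1779.41,363.42,20.42,2.32
3,1444.67,346.17,23.96,2.47
4,1601.20,95.35,5.95,5.62
5,1420.03,163.24,11.50,7.08
6,1635.72,96.56,5.90,4.19
7,1639.31,128.79,7.86,3.33
8,1382.35,69.68,5.04,4.84
9,1718.16,106.23,6.18,3.26
10,1669.79,94.98,5.69,5.05
11,430.43,72.53,16.85,2.02
12,1571.56,99.63,6.34,4.07
13,1716.63,100.73,5.87,2.12
14,1930.44,121.02,6.27,3.55
15,954.13,39.09,4.10,4.52
16,326.34,64.20,19.67,2.25
17,1097.40,53.40,4.87,4.05
18,1021.25,37.38,3.66,2.22
19,1500.33,82.06,5.47,4.37
20,2491.63,50.83,2.04,5.52
21,991.08,62.42,6.30,2.55
22,1419.06,96.21,6.78,6.52
23,1569.74,425.60,27.11,2.46
24,846.32,51.00,6.03,3.08
25,2112.42,68.64,3.25,5.28
26,2240.74,534.57,23.86,2.33
27,2128.77,66.62,3.13,3.83
28,1916.34,49.90,2.60,4.26
29,2017.23,57.77,2.86,
30,1236.79,85.88,6.94,
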