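id,lab_code,material,c14_age_bp,sigma,cal_bp_older,cal_bp_younger,period
27,BTN12002,bone,1852,20,1864,1719,Metal
3,BTN12003,bone,1880,20,1879,1737,Metal
56,BTN12004,bone,1910,20,1896,1820,Metal
4,BTN12008,bone,1925,20,1923,1823,Metal
8,BTN12009,bone,1995,20,1992,1896,Metal
58,BTN12005,bone,2015,20,2003,1899,Metal
13,BTN12001,bone,2048,20,2110,1945,Metal
2,BTN12010,bone,2150,25,2304,2046,Metal
54,BTN13023,bone,2190,20,2309,2142,Metal
43,BTN13022,bone,2290,20,2352,2206,Metal
11,WK37248,tooth dentin,2290,20,2352,2206,Metal
40,BTN12007,bone,2305,25,2356,2206,Metal
18,BTN13035,bone,2350,20,2424,2333,Metal
53,IAAA-143261,tooth dentin,2463,26,2711,2379,Neolithic
44,BTN12006,bone,2575,30,2760,2518,Neolithic
26,IAAA-170200,tooth dentin,2890,20,3136,2953,Neolithic
74,IAAA-143262,tooth dentin,4054,28,4785,4434,Pre-Neolithic
80,Beta450669,bone,4910,30,5712,5591,Pre-Neolithic
basal-charcoal,ref-layer,charcoal,13055,120,14061,13312,Late Pleistocene
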