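subject,eye,gender,age,ethnicity,spherical_equivalent_d,axial_length_mm,corneal_radius_mm,acd_mm,rmf_um_per_deg,peak_angular_density,peak_linear_density,prl_distance_arcmin,prl_distance_um,prl_angular_density,prl_linear_density
20165,L,F,28,Caucasian,0.500,22.26,7.37,3.86,261.79,13316,194625,2.83,12.34,12470,181952
20165,R,F,28,Caucasian,0.500,22.64,7.44,3.80,267.79,12714,177692,5.30,23.66,11758,163965
20177,L,F,18,Mixed,0.000,23.04,7.80,3.24,273.59,12211,162890,7.25,33.06,11476,153319
20177,R,F,18,Mixed,0.000,23.23,7.91,3.20,275.85,11999,159027,4.57,21.00,11317,148721
10003,L,M,50,Caucasian,1.000,23.30,7.80,3.12,278.81,15851,204020,7.23,33.59,13961,179594
10003,R,M,50,Caucasian,1.000,23.50,7.81,3.14,282.00,15358,193090,6.45,30.32,14869,186972
20176,L,F,18,Asian,0.000,23.45,7.98,3.65,276.50,12515,163676,18.16,83.71,8813,115273
20176,R,F,18,Asian,0.000,23.58,8.01,3.62,278.52,12312,158356,4.05,18.78,11913,153566
20172,L,F,25,Caucasian,-0.750,23.56,7.71,3.90,280.13,15516,196844,1.23,5.72,15210,193824
20172,R,F,25,Caucasian,-0.500,23.65,7.72,3.96,281.33,14976,189377,3.13,14.66,14636,184921
20147,R,M,26,Caucasian,-0.375,24.16,7.73,2.36,298.73,15537,174122,4.68,23.29,14839,166278
20147,L,M,26,Caucasian,0.000,24.17,7.81,4.03,288.94,14994,178435,11.57,55.72,13894,166422
20124,L,F,26,Asian,-3.000,24.67,7.70,4.05,298.82,13973,153998,5.17,25.77,13334,149334
20124,R,F,26,Asian,-4.250,25.29,7.68,4.07,309.88,13927,145588,2.38,12.30,13543,141033
20174,L,F,43,Caucasian,-1.750,24.80,7.79,3.57,302.57,13775,150204,7.78,39.21,11671,127480
20174,R,F,43,Caucasian,-2.750,25.37,7.83,3.62,311.85,12857,132443,6.00,31.19,11848,121826
20173,R,F,22,Caucasian,-2.750,24.96,7.81,3.68,304.64,16648,179779,7.11,36.08,15989,172286
20170,R,M,26,Asian,-2.250,25.00,7.69,3.90,305.54,14485,153681,8.98,45.73,12244,131153
20170,L,M,26,Asian,-3.750,25.66,7.65,4.15,316.25,14853,147115,1.70,8.96,14708,147060
20138,R,F,29,Caucasian,-5.000,25.26,7.95,3.14,311.22,13874,141971,6.32,32.76,12449,128530
20138,L,F,29,Caucasian,-5.000,25.28,7.91,3.15,311.92,14776,151699,5.36,27.87,14060,144506
20114,R,F,24,Asian,-5.500,25.83,8.72,3.47,310.94,14615,152657,7.00,36.29,13787,142601
20114,L,F,24,Asian,-6.000,26.16,8.98,3.58,313.31,15634,159228,4.48,23.40,15287,155729
20160,R,F,25,Asian,-5.375,25.83,7.81,3.60,320.25,15885,155083,8.25,44.06,14409,140492
20143,R,F,23,Asian,-6.875,25.91,7.42,2.10,334.12,17258,153560,3.01,16.77,16562,148354
20158,R,F,34,Asian,-6.500,26.60,7.84,3.51,333.78,13147,118491,11.82,65.76,10876,97623
20163,R,F,25,Asian,-7.125,26.84,7.89,3.65,336.60,18114,159397,3.82,21.42,17481,154287
20163,L,F,25,Asian,-7.125,27.06,7.89,3.65,340.44,19001,163731,5.02,28.50,17899,154437
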