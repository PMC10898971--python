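mid_year,n_winter,n_summer,matches,uncorrected,f_t,corrected,dyoy_pct,se,match_rate_pct
2002,1940,1252,175,13820,1.22,16875,,5955,5.80
2003,3055,3103,526,18001,1.06,19065,6.9,2981,9.34
2004,4279,3236,757,18279,1.06,19340,7.6,3027,11.20
2005,5668,3236,913,20078,1.05,21063,3.4,843,11.43
2006,5391,2465,667,19906,1.06,21095,9.1,2660,9.28
2007,5052,2707,595,22960,1.09,24915,8.0,3081,8.31
2008,3769,2519,413,22949,1.15,26456,7.4,2976,7.03
2009,3268,2684,359,24382,1.08,26445,-2.5,4369,6.42
2010,2901,2754,324,24601,0.94,23007,4.2,4328,6.08
2011,3031,2605,284,27725,1.07,29636,8.9,4885,5.31
2012,3329,2541,277,30450,1.10,33488,10.1,4455,4.95
2013,3492,2466,294,29212,1.09,31701,1.7,6193,5.19
2014,4050,2494,359,28077,1.11,31243,-0.2,4835,5.80
2015,3877,2523,334,29219,1.14,33260,-1.9,5199,5.51
2016,4110,2607,392,27282,1.09,29852,-3.0,3290,6.20
2017,4125,2364,385,25281,1.12,28429,-7.1,6319,6.31
2018,5060,2512,549,23125,1.16,26731,-4.9,3342,7.82
2019,5087,2403,552,22120,1.16,25671,0.3,4427,7.96
2020,4989,2327,484,23953,1.20,28706,-0.1,4713,7.08
2021,4773,2640,567,22198,1.20,26662,-7.1,4192,8.28
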