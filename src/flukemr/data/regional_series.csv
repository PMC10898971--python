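mid_year,region,n_winter,n_summer,matches,estimate,se,dyoy_pct
2002,Hawaii,1142,278,29,10631,2650,
2003,Hawaii,1525,1431,211,10309,996,-3.7
2004,Hawaii,2123,1743,375,9853,534,0.0
2005,Hawaii,2904,1290,352,10625,697,5.3
2006,Hawaii,3062,1097,281,11927,706,13.8
2007,Hawaii,2920,1028,209,14314,1127,10.0
2008,Hawaii,2121,1132,167,14312,1479,10.7
2009,Hawaii,1591,1195,116,16275,1338,-2.2
2010,Hawaii,1080,1107,89,13309,1703,1.3
2011,Hawaii,1104,969,71,14888,2291,4.5
2012,Hawaii,1202,956,62,18275,2572,11.7
2013,Hawaii,1364,1220,88,18728,1914,3.3
2014,Hawaii,1922,1423,164,16597,1872,-7.2
2015,Hawaii,1750,1454,176,14395,1203,-10.9
2016,Hawaii,1968,1339,197,13327,986,-8.9
2017,Hawaii,1985,1056,165,12647,1070,-5.5
2018,Hawaii,2914,1635,391,12167,730,-3.2
2019,Hawaii,3522,1784,519,12094,588,1.0
2020,Hawaii,4019,1606,496,12999,566,0.3
2021,Hawaii,4711,1593,610,12294,492,
2002,MainlandMexico,491,570,93,2990,367,
2003,MainlandMexico,588,575,112,3003,298,7.8
2004,MainlandMexico,736,604,128,3457,316,12.3
2005,MainlandMexico,906,521,113,4154,502,4.8
2006,MainlandMexico,887,371,93,3515,487,4.6
2007,MainlandMexico,838,458,96,3971,430,-0.6
2008,MainlandMexico,696,685,116,4088,459,9.6
2009,MainlandMexico,717,798,123,4627,411,6.5
2010,MainlandMexico,733,731,111,4798,536,10.1
2011,MainlandMexico,811,764,113,5450,502,6.5
2012,MainlandMexico,1146,921,188,5596,453,4.6
2013,MainlandMexico,1329,910,218,5534,478,7.4
2014,MainlandMexico,1368,975,199,6682,612,9.6
2015,MainlandMexico,1002,1632,223,7313,500,9.0
2016,MainlandMexico,1052,2098,302,7296,484,1.0
2017,MainlandMexico,1169,2223,377,6885,404,-2.0
2018,MainlandMexico,1421,2226,459,6885,337,-2.0
2019,MainlandMexico,1422,1889,390,6879,444,0.8
2020,MainlandMexico,1618,1869,429,7042,472,6.7
2021,MainlandMexico,1779,2283,490,8281,414,
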