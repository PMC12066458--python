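crop,year,grain_income,input_cost,ghg_total,neeb
wheat,2006,1125,556,7978,433
wheat,2007,1274,627,8047,510
wheat,2008,1454,662,7034,672
wheat,2009,2155,807,5144,1261
wheat,2010,1650,680,7318,845
wheat,2011,2570,865,7120,1584
wheat,2012,2234,1088,7701,1015
wheat,2013,2770,966,7407,1677
wheat,2014,2732,892,7323,1716
wheat,2015,2437,944,8027,1357
wheat,2016,2454,832,7439,1495
wheat,2017,2924,878,7473,1919
wheat,2019,2095,765,6971,1211
wheat,2020,2688,838,7322,1725
maize,2005,743,229,2986,463
maize,2006,1054,354,3217,646
maize,2007,1789,423,5361,1275
maize,2008,1562,322,3044,1188
maize,2009,2063,360,1610,1675
maize,2010,2060,530,1890,1498
maize,2011,2960,481,1721,2450
maize,2012,3203,1101,4236,2030
maize,2013,2881,859,3143,1969
maize,2014,3503,798,5707,2607
maize,2015,1899,590,2554,1266
maize,2016,2438,738,2504,1657
maize,2017,2413,520,2120,1857
maize,2019,2747,681,2124,2031
maize,2020,4210,658,2762,3505
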