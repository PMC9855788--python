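ad,total_area_km2,current,ssp245_2021_2040,ssp245_2041_2060,ssp245_2061_2080,ssp245_2081_2100,ssp585_2021_2040,ssp585_2041_2060,ssp585_2061_2080,ssp585_2081_2100
Busan,193.5,0,0,0,162,180,0,0,184.5,189
North Chungcheong,1926,0,0,0,1161,1453.5,0,22.5,1624.5,1773
South Chungcheong,2115,18,45,81,1264.5,1458,99,225,1593,1993.5
Daegu,220.5,31.5,85.5,108,198,207,112.5,130.5,207,216
Daejeon,144,0,0,4.5,144,144,18,54,144,144
Gangwon,4392,0,0,13.5,283.5,418.5,0,0,504,886.5
Gwangju,130.5,54,63,117,130.5,130.5,94.5,117,130.5,130.5
Gyeonggi,2695.5,0,0,0,193.5,306,0,0,378,1057.5
North Gyeongsang,4963.5,193.5,333,1152,3838.5,4140,972,1381.5,4351.5,4599
South Gyeongsang,2709,0,18,135,2178,2358,144,378,2331,2524.5
Incheon,261,0,0,0,0,0,0,0,0,0
Jeju,459,0,0,4.5,292.5,310.5,0,0,301.5,337.5
North Jeolla,2052,220.5,369,648,1737,1813.5,594,796.5,1836,1944
South Jeolla,3055.5,40.5,157.5,504,2484,2664,306,580.5,2637,2907
Sejong,117,0,0,0,99,117,0,0,117,117
Seoul,148.5,0,0,0,0,0,0,0,0,36
Ulsan,274.5,0,13.5,45,234,243,27,27,243,256.5
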