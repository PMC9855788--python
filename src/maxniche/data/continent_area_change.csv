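continent,current_area_km2,ssp245_2021_2040,ssp245_2041_2060,ssp245_2061_2080,ssp245_2081_2100,ssp585_2021_2040,ssp585_2041_2060,ssp585_2061_2080,ssp585_2081_2100
Africa,4063351.5,-0.28,-16.59,7.92,8.75,1.11,0.13,10.04,10.94
Antarctica,0,0,0,0,0,0,0,0,0
Asia,2225502,2.82,8.33,28.24,30.92,8.27,11.89,32.29,38.12
Australia,1641442.5,5.52,-1.41,9.03,9.29,0.24,-3.37,8.88,9.29
Europe,463756.5,-13.55,34.49,53.18,61.05,-8.59,-26.40,71.78,56.65
North America,1416852,1.58,0.96,17.73,20.14,-0.29,0.64,17.86,22.05
Oceania,55350,7.13,10.82,32.21,34.30,-0.78,-7.79,28.15,26.76
South America,3309093,-0.89,-6.05,5.15,5.68,1.80,1.83,5.24,5.66
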